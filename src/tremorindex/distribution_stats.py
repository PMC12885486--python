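"""Distribution-shape statistics of Tremor Index values.

Free-living TI values are long-tailed: most ST windows hold rest or quiet
activity (near-zero level energy) and a minority hold tremor bursts.  The
per-hand distributions are summarised three ways: a lambda-bin probability
density (linear bins over [0, max TI]), a least-squares line fitted to the
PDF in log-log coordinates (slope/intercept of the tail law), and the
Pearson kurtosis (normal = 3) and skewness of the raw values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, EmptyDataError, UndefinedMomentsError

DEFAULT_NBINS = 20


@dataclass
class BinnedPDF:
    """Probability density of TI values over ``len(centers)`` linear bins."""

    edges: np.ndarray
    centers: np.ndarray
    probabilities: np.ndarray
    n: int


@dataclass
class LogLogFit:
    slope: float
    intercept: float
    r_squared: float


@dataclass
class ShapeMoments:
    """Pearson kurtosis (normal = 3) and standardized skewness."""

    kurtosis: float
    skewness: float


def ti_histogram(
    values, nbins: int = DEFAULT_NBINS, hi: float | None = None
) -> BinnedPDF:
    """Bin TI values into ``nbins`` linear bins spanning [0, max].

    ``hi`` overrides the upper edge so two hands can share one grid (the
    pooled maximum); values above ``hi`` would be a caller bug and raise.
    Zero-valued windows are data (rest periods) and are binned like any
    other value.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyDataError("cannot bin an empty set of TI values")
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValueError("TI values must be finite and non-negative")
    top = float(np.max(values)) if hi is None else float(hi)
    if np.any(values > top * (1 + 1e-12)):
        raise ValueError("values exceed the requested upper bin edge")
    if top <= 0:  # all-zero values: one occupied bin over a unit span
        top = 1.0
    edges = np.linspace(0.0, top, nbins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return BinnedPDF(
        edges=edges,
        centers=0.5 * (edges[:-1] + edges[1:]),
        probabilities=counts / values.size,
        n=int(values.size),
    )


def loglog_regression(pdf: BinnedPDF) -> LogLogFit:
    """OLS of log10(probability) on log10(bin centre), empty bins dropped."""
    mask = (pdf.probabilities > 0) & (pdf.centers > 0)
    if int(mask.sum()) < 2:
        raise DegenerateFitError(
            f"log-log fit needs >= 2 occupied bins with positive centres, "
            f"got {int(mask.sum())}"
        )
    x = np.log10(pdf.centers[mask])
    y = np.log10(pdf.probabilities[mask])
    res = stats.linregress(x, y)
    return LogLogFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def shape_moments(values) -> ShapeMoments:
    """Standardized third/fourth central moments, bias-uncorrected."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise UndefinedMomentsError("need at least 4 values for shape moments")
    if np.var(values) == 0:
        raise UndefinedMomentsError("shape moments undefined for zero variance")
    return ShapeMoments(
        kurtosis=float(stats.kurtosis(values, fisher=False, bias=True)),
        skewness=float(stats.skew(values, bias=True)),
    )


def shape_summary_frame(ti_by_hand_freq: dict[str, dict[int, np.ndarray]],
                        nbins: int = DEFAULT_NBINS) -> pd.DataFrame:
    """Per hand x frequency summary of the pooled TI distribution.

    ``ti_by_hand_freq`` maps hand label -> frequency -> pooled valid TI
    values across all kept day segments.  Columns mirror the usual report:
    hand, f_hz, slope, intercept, r_squared, kurtosis, skewness, n_windows.
    """
    rows = []
    for hand, per_f in ti_by_hand_freq.items():
        for f in sorted(per_f):
            vals = np.asarray(per_f[f], dtype=float)
            row = {"hand": hand, "f_hz": f, "n_windows": int(vals.size)}
            try:
                fit = loglog_regression(ti_histogram(vals, nbins))
                row.update(slope=fit.slope, intercept=fit.intercept,
                           r_squared=fit.r_squared)
            except (EmptyDataError, DegenerateFitError):
                row.update(slope=np.nan, intercept=np.nan, r_squared=np.nan)
            try:
                m = shape_moments(vals)
                row.update(kurtosis=m.kurtosis, skewness=m.skewness)
            except UndefinedMomentsError:
                row.update(kurtosis=np.nan, skewness=np.nan)
            rows.append(row)
    cols = ["hand", "f_hz", "slope", "intercept", "r_squared",
            "kurtosis", "skewness", "n_windows"]
    return pd.DataFrame(rows, columns=cols)
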