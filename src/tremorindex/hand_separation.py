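"""Inter-hand separation of TI distributions and the clinical association.

For each frequency f the two hands' binned TI densities are compared
along the *second-highest* bin: the tallest bin of a free-living TI
distribution is the rest/quiet mode near zero, so the second peak is where
tremor mass accumulates.  The log distance

    D_f = log10(bin_f^T) - log10(bin_f^nT)

is positive when the most-affected hand's second peak sits at higher TI.  A
frequency counts as separated (c_f = 1) when the peaks are at least 30% of
the maximum TI at f apart; C = sum_f c_f counts separated frequencies.

A flagging rule that compares the log-scale distance D_f against the
linear quantity 0.3 max TI_f would mix scales; the default rule keeps
dimensional consistency by thresholding the *linear* peak distance
(bin_T - bin_nT >= 0.3 max TI_f) while still reporting D_f on the log
scale.  The literal log-scale rule is selectable, and results record which
rule was applied.

The clinical anchor is the tremor symptom load of the affected hand,
L = (number of present tremor types) x (sum of their MDS-UPDRS item
intensities) over {postural, kinetic, rest}, range 0-36.  C and L are
normalized to 0-10 by their theoretical maxima before the Pearson
correlation, the paired t-test and the 95% CI of the C - L differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .distribution_stats import BinnedPDF, ti_histogram
from .errors import (
    DegenerateDistributionError,
    EmptyDataError,
    LogDomainError,
    ValidationError,
)

TREMOR_TYPES = ("postural", "kinetic", "rest")
MAX_SYMPTOM_LOAD = 36  # 3 types x (3 x 4 intensity)
SEPARATION_FRACTION = 0.3


@dataclass
class ClinicalScores:
    """MDS-UPDRS part III tremor item intensities (0-4) for one hand."""

    postural: int = 0
    kinetic: int = 0
    rest: int = 0

    def __post_init__(self) -> None:
        for k in TREMOR_TYPES:
            v = getattr(self, k)
            if v not in (0, 1, 2, 3, 4):
                raise ValidationError(
                    f"{k} tremor intensity must be an integer 0-4, got {v!r}"
                )

    @property
    def intensities(self) -> tuple[int, int, int]:
        return (self.postural, self.kinetic, self.rest)


def symptom_load(scores: ClinicalScores) -> int:
    """L = (number of present types) x (sum of intensities); range 0-36."""
    present = sum(1 for v in scores.intensities if v > 0)
    return present * sum(scores.intensities)


def second_peak_bin(pdf: BinnedPDF) -> float:
    """TI location (bin centre) of the second-largest-probability bin.

    Ties are broken toward the lower-TI bin.
    """
    occupied = int(np.sum(pdf.probabilities > 0))
    if occupied < 2:
        raise DegenerateDistributionError(
            f"need >= 2 occupied bins for a second peak, got {occupied}"
        )
    order = sorted(
        range(len(pdf.probabilities)),
        key=lambda i: (-pdf.probabilities[i], pdf.centers[i]),
    )
    return float(pdf.centers[order[1]])


def hand_distance(
    pdf_t: BinnedPDF, pdf_nt: BinnedPDF
) -> tuple[float, float, float]:
    """(D_f, bin_T, bin_nT): log10 distance between second-peak locations."""
    b_t = second_peak_bin(pdf_t)
    b_nt = second_peak_bin(pdf_nt)
    if b_t <= 0 or b_nt <= 0:
        raise LogDomainError(
            f"second-peak bins must be positive for the log distance, "
            f"got {b_t} and {b_nt}"
        )
    return math.log10(b_t) - math.log10(b_nt), b_t, b_nt


@dataclass
class SeparationResult:
    """Per-frequency separation of one participant's two hands."""

    d_f: dict[int, float]
    bin_t: dict[int, float]
    bin_nt: dict[int, float]
    c_f: dict[int, int]
    C: int
    threshold_rule: str
    skipped: list[int] = field(default_factory=list)


def separated_count(
    distances: dict[int, tuple[float, float, float]],
    ti_max: dict[int, float],
    rule: str = "linear",
    fraction: float = SEPARATION_FRACTION,
) -> SeparationResult:
    """Flag separated frequencies and count them.

    ``distances`` maps f -> (D_f, bin_T, bin_nT) (or None for frequencies
    where either hand's distribution was degenerate; those are excluded from
    C with a warning).  ``ti_max[f]`` is the maximum valid TI observed at f
    across both hands.  ``rule`` is ``"linear"`` (default: linear peak
    distance vs 0.3 max TI) or ``"literal"`` (log distance vs 0.3 max TI).
    """
    if rule not in ("linear", "literal"):
        raise ValueError("rule must be 'linear' or 'literal'")
    d_f: dict[int, float] = {}
    bin_t: dict[int, float] = {}
    bin_nt: dict[int, float] = {}
    c_f: dict[int, int] = {}
    skipped: list[int] = []
    for f in sorted(distances):
        entry = distances[f]
        if entry is None:
            skipped.append(f)
            warnings.warn(
                f"f={f} Hz: missing or degenerate PDF for one hand; "
                "excluded from C",
                stacklevel=2,
            )
            continue
        df, bt, bnt = entry
        d_f[f], bin_t[f], bin_nt[f] = df, bt, bnt
        threshold = fraction * ti_max[f]
        measure = (bt - bnt) if rule == "linear" else df
        c_f[f] = int(measure >= threshold - 1e-12)
    return SeparationResult(
        d_f=d_f,
        bin_t=bin_t,
        bin_nt=bin_nt,
        c_f=c_f,
        C=int(sum(c_f.values())),
        threshold_rule=f"{rule}:{fraction:g}*max(TI_f)",
        skipped=skipped,
    )


def separate_hands(
    ti_t: dict[int, np.ndarray],
    ti_nt: dict[int, np.ndarray],
    nbins: int = 20,
    rule: str = "linear",
    fraction: float = SEPARATION_FRACTION,
) -> SeparationResult:
    """Full separation analysis from pooled valid TI values per hand.

    ``ti_t`` / ``ti_nt`` map frequency -> pooled TI values (tiu) of the
    most / least affected hand.  Each hand's PDF is binned over its own
    [0, max] range (a grid pooled across hands would collapse a quiet
    hand's whole distribution into one bin); the separation threshold is
    still referenced to the pooled maximum TI at f across both hands.
    """
    distances: dict[int, tuple[float, float, float] | None] = {}
    ti_max: dict[int, float] = {}
    for f in sorted(set(ti_t) & set(ti_nt)):
        vt = np.asarray(ti_t[f], dtype=float)
        vnt = np.asarray(ti_nt[f], dtype=float)
        if vt.size == 0 or vnt.size == 0:
            distances[f] = None
            ti_max[f] = np.nan
            continue
        ti_max[f] = float(max(vt.max(), vnt.max()))
        try:
            pdf_t = ti_histogram(vt, nbins)
            pdf_nt = ti_histogram(vnt, nbins)
            distances[f] = hand_distance(pdf_t, pdf_nt)
        except (DegenerateDistributionError, LogDomainError, EmptyDataError):
            distances[f] = None
    return separated_count(distances, ti_max, rule=rule, fraction=fraction)


@dataclass
class AssociationResult:
    """Pearson C-L association with its paired-difference verification."""

    pearson_r: float
    pearson_p: float
    mean_diff: float
    ci95: tuple[float, float]
    ttest_p: float
    n: int


def associate(
    c_list, l_list, freq_count: int = 10
) -> AssociationResult:
    """Correlate separated-frequency counts with symptom loads.

    Both are normalized to 0-10 by their theoretical maxima (``freq_count``
    frequencies; L max 36), then Pearson r, the mean C - L difference with
    its 95% t-interval, and a paired-samples t-test are computed.
    """
    c = np.asarray(c_list, dtype=float) * 10.0 / freq_count
    l = np.asarray(l_list, dtype=float) * 10.0 / MAX_SYMPTOM_LOAD
    if c.shape != l.shape or c.ndim != 1:
        raise ValueError("C and L lists must be aligned 1-D sequences")
    n = c.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(c) == 0 or np.std(l) == 0:
        raise EmptyDataError(
            "correlation undefined: zero variance in C or L"
        )
    r, p = stats.pearsonr(c, l)
    diff = c - l
    mean_diff = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    if sd == 0:
        ci = (mean_diff, mean_diff)
        t_p = 1.0 if mean_diff == 0 else 0.0
    else:
        half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
        ci = (mean_diff - half, mean_diff + half)
        t_p = float(stats.ttest_rel(c, l).pvalue)
    return AssociationResult(
        pearson_r=float(r),
        pearson_p=float(p),
        mean_diff=mean_diff,
        ci95=ci,
        ttest_p=t_p,
        n=int(n),
    )
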