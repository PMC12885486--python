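"""Elevation-angle construction and per-frequency wavelet level extraction.

The whole tremor pipeline runs on a single scalar signal: the elevation
angle theta = arctan(a_z / 1) of the wrist, with the forearm fixed at unit
length.  The Oz accelerometer axis (perpendicular to the palm plane) carries
flexion/extension and rolling components of tremor while being the axis
least excited by common daily activities, so Ox and Oy are discarded.

A wavelet level assigned to an integer target frequency f in 3..12 Hz is the
*first detail band* of a shift-invariant Daubechies decomposition taken at a
per-frequency sampling rate fs_f = 8f/3 Hz: the first dyadic detail band is
(fs_f/4, fs_f/2], whose geometric-arithmetic centre 3 fs_f / 8 is then
exactly f.  All ratios from the device rate of 32 Hz are small rationals
(fs_f/32 = f/12), so resampling is exact polyphase work.  Slow daily-motion
content is left to the depth-J smooth and never enters the tremor index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pywt
from scipy.signal import resample_poly

from ._modwt import detail1, mra_components, smooth as smooth_mra
from ._timebase import chunk_table
from .e4_io import RawAccelRecording
from .errors import DomainError, LengthError

FREQUENCY_SET = tuple(range(3, 13))
DEFAULT_WAVELET = "db4"
DEFAULT_DEPTH = 4


@dataclass
class ElevationSeries:
    """Elevation angle samples (radians) with gap-aware timing."""

    theta: np.ndarray
    fs: float
    start_epoch: float
    gaps: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)

    def chunks(self) -> list[tuple[float, int, int]]:
        return chunk_table(self.start_epoch, len(self.theta), self.fs, self.gaps)


@dataclass
class LevelSeries:
    """The wavelet detail signal assigned to one target frequency.

    ``values`` holds the first-detail amplitudes (radians) at the
    per-frequency rate ``fs_f``; ``band`` is the nominal dyadic band
    (fs_f/4, fs_f/2] whose centre is ``f``.  ``valid`` flags samples far
    enough from chunk boundaries to be free of filter edge transients;
    ``smooth`` (optional) is the co-indexed depth-J smooth.
    """

    f: int
    fs_f: float
    start_epoch: float
    values: np.ndarray
    valid: np.ndarray
    band: tuple[float, float]
    gaps: list[tuple[float, float]] = field(default_factory=list)
    smooth: np.ndarray | None = None

    def chunks(self) -> list[tuple[float, int, int]]:
        return chunk_table(self.start_epoch, len(self.values), self.fs_f, self.gaps)


def elevation(rec: RawAccelRecording) -> ElevationSeries:
    """theta = arctan(a_z / 1), in radians; only the Oz axis is used."""
    return ElevationSeries(
        theta=np.arctan(rec.az),
        fs=rec.fs,
        start_epoch=rec.start_epoch,
        gaps=list(rec.gaps),
    )


def target_rate(f: int) -> float:
    """Sampling rate (Hz) that centres the first detail band on ``f``.

    fs_f = 8f/3, so the band (fs_f/4, fs_f/2] = (2f/3, 4f/3] has centre f.
    """
    if f != int(f) or not 3 <= int(f) <= 12:
        raise DomainError(f"target frequency must be an integer in [3, 12], got {f}")
    return 8 * int(f) / 3


def target_ratio(f: int, fs_in: float = 32.0) -> Fraction:
    """Exact rational resampling ratio fs_f / fs_in."""
    target = Fraction(8 * int(f), 3)
    ratio = target / Fraction(fs_in).limit_denominator(10**6)
    if ratio > 1:
        raise DomainError(
            f"target rate {float(target):g} Hz exceeds input rate {fs_in:g} Hz"
        )
    if ratio.numerator > 64 or ratio.denominator > 64:
        raise DomainError(
            f"no small rational ratio from {fs_in:g} Hz to {float(target):g} Hz"
        )
    return ratio


def _resample_chunk(x: np.ndarray, ratio: Fraction) -> np.ndarray:
    if ratio == 1:
        return np.asarray(x, dtype=float)
    return resample_poly(x, ratio.numerator, ratio.denominator)


def resample(series: ElevationSeries, fs_out: float) -> ElevationSeries:
    """Anti-aliased rational-ratio resampling, gap-aware.

    Each contiguous chunk is resampled independently; the filter never
    crosses a gap.  Output duration matches input duration to within one
    sample period per chunk.
    """
    ratio = Fraction(fs_out).limit_denominator(10**6) / Fraction(
        series.fs
    ).limit_denominator(10**6)
    if ratio > 1:
        raise DomainError("upsampling is not supported")
    if ratio.denominator > 256:
        raise DomainError(
            f"resampling ratio {series.fs:g} -> {fs_out:g} Hz is not a small rational"
        )
    fs_new = series.fs * float(ratio)
    parts = []
    spans: list[tuple[float, int]] = []
    for (tc, a, b) in series.chunks():
        y = _resample_chunk(series.theta[a:b], ratio)
        parts.append(y)
        spans.append((tc, len(y)))
    gaps = [
        (tc + n / fs_new, tc_next)
        for (tc, n), (tc_next, _) in zip(spans, spans[1:])
    ]
    return ElevationSeries(
        theta=np.concatenate(parts) if parts else np.empty(0),
        fs=fs_new,
        start_epoch=spans[0][0] if spans else series.start_epoch,
        gaps=gaps,
    )


def min_length(wavelet: str = DEFAULT_WAVELET, depth: int = DEFAULT_DEPTH) -> int:
    """Shortest series accepted for a depth-``depth`` decomposition."""
    L = pywt.Wavelet(wavelet).dec_len
    return (L - 1) * 2**depth


def edge_samples(wavelet: str = DEFAULT_WAVELET) -> int:
    """Samples flagged at each chunk boundary of a first-detail level.

    The composite analysis+synthesis kernel of the first detail spans
    2L - 1 samples, and the polyphase resampler contributes a boundary
    transient of ~10 output samples; three filter lengths cover both with
    margin.
    """
    return 3 * pywt.Wavelet(wavelet).dec_len


def mra(
    x: np.ndarray, wavelet: str = DEFAULT_WAVELET, depth: int = DEFAULT_DEPTH
) -> tuple[list[np.ndarray], np.ndarray]:
    """Additive multi-resolution decomposition of one contiguous signal.

    Returns ``([D1..DJ], smooth)`` with ``sum(details) + smooth == x`` to
    numerical precision.  Detail j occupies the nominal dyadic band
    (fs/2**(j+1), fs/2**j].  Boundaries are handled by reflection extension.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    need = min_length(wavelet, depth)
    if n < need:
        raise LengthError(
            f"series of length {n} too short for depth {depth} "
            f"(minimum {need} samples)",
            min_length=need,
        )
    L = pywt.Wavelet(wavelet).dec_len
    pad = min(n - 1, (L - 1) * (2**depth - 1) + L)
    xe = np.pad(x, pad, mode="reflect")
    details, sm = mra_components(xe, wavelet, depth)
    sl = slice(pad, pad + n)
    return [d[sl] for d in details], sm[sl]


def _detail1_padded(x: np.ndarray, wavelet: str) -> np.ndarray:
    L = pywt.Wavelet(wavelet).dec_len
    pad = min(len(x) - 1, 4 * L)
    xe = np.pad(x, pad, mode="reflect")
    return detail1(xe, wavelet)[pad : pad + len(x)]


def _smooth_padded(x: np.ndarray, wavelet: str, depth: int) -> np.ndarray:
    L = pywt.Wavelet(wavelet).dec_len
    pad = min(len(x) - 1, (L - 1) * (2**depth - 1) + L)
    xe = np.pad(x, pad, mode="reflect")
    return smooth_mra(xe, wavelet, depth)[pad : pad + len(x)]


def level_for_frequency(
    series: ElevationSeries,
    f: int,
    wavelet: str = DEFAULT_WAVELET,
    depth: int = DEFAULT_DEPTH,
    include_smooth: bool = False,
) -> LevelSeries:
    """Extract the wavelet level assigned to target frequency ``f``.

    Resamples to fs_f = 8f/3 Hz and takes the first detail of a
    shift-invariant decomposition, chunk by chunk.  Chunks shorter than the
    decomposition minimum are skipped (they become gaps).  Samples within
    :func:`edge_samples` of a chunk boundary are flagged invalid.
    """
    ratio = target_ratio(f, series.fs)
    fs_f = series.fs * float(ratio)
    need = min_length(wavelet, depth)
    edge = edge_samples(wavelet)
    values_parts: list[np.ndarray] = []
    smooth_parts: list[np.ndarray] = []
    valid_parts: list[np.ndarray] = []
    spans: list[tuple[float, int]] = []
    for (tc, a, b) in series.chunks():
        y = _resample_chunk(series.theta[a:b], ratio)
        if len(y) < need:
            continue
        d1 = _detail1_padded(y, wavelet)
        ok = np.ones(len(y), dtype=bool)
        ok[:edge] = False
        ok[len(y) - edge :] = False
        values_parts.append(d1)
        valid_parts.append(ok)
        if include_smooth:
            smooth_parts.append(_smooth_padded(y, wavelet, depth))
        spans.append((tc, len(y)))
    gaps = [
        (tc + n / fs_f, tc_next) for (tc, n), (tc_next, _) in zip(spans, spans[1:])
    ]
    return LevelSeries(
        f=int(f),
        fs_f=fs_f,
        start_epoch=spans[0][0] if spans else series.start_epoch,
        values=np.concatenate(values_parts) if values_parts else np.empty(0),
        valid=np.concatenate(valid_parts) if valid_parts else np.empty(0, dtype=bool),
        band=(fs_f / 4, fs_f / 2),
        gaps=gaps,
        smooth=(
            np.concatenate(smooth_parts)
            if include_smooth and smooth_parts
            else None
        ),
    )
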