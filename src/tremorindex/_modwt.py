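"""Shift-invariant (undecimated) Daubechies wavelet transform primitives.

This is a maximal-overlap discrete wavelet transform in its orthonormal
normalisation (filters divided by sqrt(2) per level), implemented with
circular a-trous filtering so every level has the length of the input and
the additive multi-resolution components are exact.  The conventions match
``pywt.swt(..., norm=True)`` / ``pywt.mra(..., transform="swt")`` sample for
sample (the test suite cross-checks this), but reconstruction here is
*selective*: the tremor pipeline only ever needs the first detail band and,
occasionally, the depth-J smooth, so reconstructing every level the way
``pywt.mra`` does would waste an order of magnitude of work on multi-day
recordings.

Boundary handling is the caller's business: these functions are circular and
callers pad (by reflection) and trim.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.ndimage import convolve1d


def _filters(wavelet: str | pywt.Wavelet) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(wavelet) if isinstance(wavelet, str) else wavelet
    s = np.sqrt(2.0)
    return np.asarray(w.dec_lo) / s, np.asarray(w.dec_hi) / s


def _apply(x: np.ndarray, filt: np.ndarray, level: int, adjoint: bool) -> np.ndarray:
    """One circular a-trous filtering pass at ``level`` (1-based).

    The analysis pass at level j is circular correlation with the filter
    upsampled by 2**(j-1) and centred (shift 2**(j-1) * L/2);
    ``adjoint=True`` applies the transpose, which is the synthesis direction
    of an orthonormal transform.
    """
    step = 2 ** (level - 1)
    shift = step * (len(filt) // 2)
    kernel = np.zeros(step * (len(filt) - 1) + 1)
    kernel[::step] = filt
    nk = len(kernel)
    if adjoint:
        return convolve1d(x, kernel[::-1], mode="wrap",
                          origin=nk - 1 - shift - nk // 2)
    return convolve1d(x, kernel, mode="wrap", origin=shift - nk // 2)


def analysis(x: np.ndarray, wavelet, level: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Full decomposition: detail coefficients [W1..WJ] and approximation VJ."""
    lo, hi = _filters(wavelet)
    v = np.asarray(x, dtype=float)
    details = []
    for j in range(1, level + 1):
        details.append(_apply(v, hi, j, adjoint=False))
        v = _apply(v, lo, j, adjoint=False)
    return details, v


def mra_components(x: np.ndarray, wavelet, level: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Additive components ([D1..DJ], smooth); their sum equals ``x`` exactly."""
    lo, hi = _filters(wavelet)
    coeffs, vj = analysis(x, wavelet, level)
    details = []
    for j, w in enumerate(coeffs, start=1):
        y = _apply(w, hi, j, adjoint=True)
        for k in range(j - 1, 0, -1):
            y = _apply(y, lo, k, adjoint=True)
        details.append(y)
    s = vj
    for k in range(level, 0, -1):
        s = _apply(s, lo, k, adjoint=True)
    return details, s


def detail1(x: np.ndarray, wavelet) -> np.ndarray:
    """First-detail MRA component only (band (fs/4, fs/2]); two passes."""
    _, hi = _filters(wavelet)
    w1 = _apply(np.asarray(x, dtype=float), hi, 1, adjoint=False)
    return _apply(w1, hi, 1, adjoint=True)


def smooth(x: np.ndarray, wavelet, level: int) -> np.ndarray:
    """Depth-``level`` smooth MRA component only (band [0, fs/2**(J+1)])."""
    lo, _ = _filters(wavelet)
    v = np.asarray(x, dtype=float)
    for j in range(1, level + 1):
        v = _apply(v, lo, j, adjoint=False)
    for k in range(level, 0, -1):
        v = _apply(v, lo, k, adjoint=True)
    return v
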