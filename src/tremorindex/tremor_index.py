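"""The Tremor Index: wavelet-level energy per sampling-time (ST) window.

For the level assigned to frequency f, the index over one ST window of
q = ST * fs_f samples is

    TI_f = beta * sum_{i=1..q} theta_f(i)^2

with beta = 1e4 by default so that, with theta_f in radians, TI is reported
in tremor index units (1 tiu = 100 mrad^2 per ST window: 10^6 mrad^2/rad^2
divided by 100).  Windows are non-overlapping and aligned to wall-clock
multiples of ST (quarter hours for the 15-minute default), matching typical
on-the-hour / half-past medication schedules.  A window is valid only if all
q of its level samples exist and are free of gap or filter-edge
contamination; partial windows are never scaled up, they are flagged
invalid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, time, timedelta
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .decomposition import (
    DEFAULT_DEPTH,
    DEFAULT_WAVELET,
    FREQUENCY_SET,
    LevelSeries,
    elevation,
    level_for_frequency,
)
from .e4_io import RawAccelRecording
from .segmentation import DaySegment

DEFAULT_ST_MINUTES = 15
DEFAULT_BETA = 1e4


@dataclass
class TISeries:
    """Tremor Index values per ST window for one frequency.

    ``values`` is in tiu and NaN where ``valid`` is False.
    """

    f: int
    st_minutes: float
    beta: float
    fs_f: float
    window_starts: np.ndarray  # Unix epoch seconds
    values: np.ndarray
    valid: np.ndarray

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


def tremor_index(
    level: LevelSeries,
    st_minutes: float = DEFAULT_ST_MINUTES,
    beta: float = DEFAULT_BETA,
    window_starts: np.ndarray | None = None,
) -> TISeries:
    """Compute TI over non-overlapping ST windows of a level series.

    If ``window_starts`` is not given, windows are anchored at Unix-epoch
    multiples of ``st_minutes`` covering the series span.  Each window needs
    exactly ``q = st_minutes * 60 * fs_f`` samples inside one contiguous
    chunk, all unflagged; otherwise it is invalid.
    """
    if st_minutes <= 0:
        raise ValueError("st_minutes must be positive")
    step = st_minutes * 60.0
    q_exact = step * level.fs_f
    q = int(round(q_exact))
    if abs(q_exact - q) > 1e-6:
        raise ValueError(
            f"ST of {st_minutes} min is not an integer number of samples at "
            f"{level.fs_f:g} Hz"
        )
    chunks = level.chunks()
    if window_starts is None:
        if not chunks:
            window_starts = np.empty(0)
        else:
            t_lo = chunks[0][0]
            t_hi = chunks[-1][0] + (chunks[-1][2] - chunks[-1][1]) / level.fs_f
            w0 = np.floor(t_lo / step) * step
            window_starts = np.arange(w0, t_hi, step)
    window_starts = np.asarray(window_starts, dtype=float)
    values = np.full(len(window_starts), np.nan)
    valid = np.zeros(len(window_starts), dtype=bool)
    if q == 0 or len(window_starts) == 0:
        return TISeries(level.f, st_minutes, beta, level.fs_f,
                        window_starts, values, valid)
    any_valid = False
    for (tc, a, b) in chunks:
        n = b - a
        if n < q:
            continue
        i0 = np.round((window_starts - tc) * level.fs_f).astype(np.int64)
        inside = (i0 >= 0) & (i0 + q <= n)
        if not np.any(inside):
            continue
        vals = level.values[a:b]
        ok = level.valid[a:b]
        csq = np.concatenate([[0.0], np.cumsum(vals * vals)])
        cok = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
        ii = i0[inside]
        full = (cok[ii + q] - cok[ii]) == q
        sel = np.flatnonzero(inside)[full]
        values[sel] = beta * (csq[ii[full] + q] - csq[ii[full]])
        valid[sel] = True
        any_valid = any_valid or bool(full.any())
    if len(window_starts) and not any_valid:
        warnings.warn(
            f"no ST window of {st_minutes} min fully covered at f={level.f} Hz; "
            "all windows invalid",
            stacklevel=2,
        )
    return TISeries(level.f, st_minutes, beta, level.fs_f,
                    window_starts, values, valid)


def day_window_starts(
    segments: list[DaySegment], tz: str | ZoneInfo, st_minutes: float
) -> np.ndarray:
    """Wall-clock-aligned window start epochs covering each segment's day."""
    if isinstance(tz, str):
        tz = ZoneInfo(tz)
    step = st_minutes * 60.0
    starts = []
    for seg in segments:
        t0 = datetime.combine(seg.date, time(0, 0), tzinfo=tz).timestamp()
        t1 = datetime.combine(
            seg.date + timedelta(days=1), time(0, 0), tzinfo=tz
        ).timestamp()
        starts.append(np.arange(t0, t1 - 1e-6, step))
    return np.concatenate(starts) if starts else np.empty(0)


def ti_profile(
    rec: RawAccelRecording,
    segments: list[DaySegment],
    frequencies=FREQUENCY_SET,
    st_minutes: float = DEFAULT_ST_MINUTES,
    beta: float = DEFAULT_BETA,
    tz: str | ZoneInfo = "UTC",
    wavelet: str = DEFAULT_WAVELET,
    depth: int = DEFAULT_DEPTH,
) -> dict[int, TISeries]:
    """Full 24-hour TI coverage of the kept day segments, per frequency.

    Decomposition runs once over the whole recording (so chunk boundaries,
    not day boundaries, decide edge flagging); windows are then laid on each
    kept day's local wall-clock quarter-hour grid, nighttime included.
    """
    if not segments:
        return {}
    theta = elevation(rec)
    ws = day_window_starts(segments, tz, st_minutes)
    out: dict[int, TISeries] = {}
    for f in frequencies:
        level = level_for_frequency(theta, f, wavelet=wavelet, depth=depth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[int(f)] = tremor_index(
                level, st_minutes=st_minutes, beta=beta, window_starts=ws
            )
    return out


def ti_to_frame(
    profile: dict[int, TISeries],
    hand: str,
    tz: str | ZoneInfo = "UTC",
) -> pd.DataFrame:
    """Long-format table: hand, date, window_start_iso, f_hz, ti_tiu, valid."""
    if isinstance(tz, str):
        tz = ZoneInfo(tz)
    frames = []
    for f in sorted(profile):
        s = profile[f]
        when = [datetime.fromtimestamp(t, tz) for t in s.window_starts]
        frames.append(
            pd.DataFrame(
                {
                    "hand": hand,
                    "date": [w.date().isoformat() for w in when],
                    "window_start_iso": [w.isoformat() for w in when],
                    "f_hz": f,
                    "ti_tiu": s.values,
                    "valid": s.valid,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["hand", "date", "window_start_iso", "f_hz", "ti_tiu", "valid"]
        )
    return pd.concat(frames, ignore_index=True)
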