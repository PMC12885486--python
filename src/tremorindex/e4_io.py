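"""Reading, calibrating and stitching Empatica-E4-style accelerometer CSVs.

The on-disk dialect is the E4 ``ACC.csv`` layout: line 1 holds the Unix start
timestamp in seconds, line 2 the sampling rate in Hz (nominally 32), and every
following line one ``x,y,z`` sample in raw counts of 1/64 g.  Calibration is a
single division by 64.  Recordings retrieved in multi-file sessions are
stitched into one continuous object whose ``gaps`` field records every
inter-file interval; no sample is ever interpolated across a gap, because the
downstream day-completeness filter needs true missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._timebase import chunk_table
from .errors import (
    EmptyRecordingError,
    FormatError,
    IncompatibilityError,
    OverlapError,
)

COUNTS_PER_G = 64.0

HAND_LABELS = ("T", "nT", "unknown")


@dataclass
class RawAccelRecording:
    """One hand's calibrated three-axis acceleration stream.

    Samples are stored as the concatenation of contiguous *chunks* separated
    by the intervals in ``gaps``.  Sample ``i`` of a chunk starting at epoch
    ``t0`` is timestamped ``t0 + i / fs``.  ``hand_label`` is ``"T"`` for the
    most tremor-affected hand, ``"nT"`` for the least affected one.
    """

    start_epoch: float
    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    hand_label: str = "unknown"
    gaps: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise ValueError("ax, ay, az must have identical lengths")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.isfinite(self.start_epoch):
            raise ValueError("start_epoch must be finite")
        if self.hand_label not in HAND_LABELS:
            raise ValueError(f"hand_label must be one of {HAND_LABELS}")
        self.gaps = [(float(a), float(b)) for a, b in self.gaps]
        for (a, b) in self.gaps:
            if not b > a:
                raise ValueError(f"gap [{a}, {b}) is empty or reversed")
        for (_, b0), (a1, _) in zip(self.gaps, self.gaps[1:]):
            if a1 < b0:
                raise ValueError("gaps must be disjoint and sorted")

    @property
    def n_samples(self) -> int:
        return len(self.az)

    def chunks(self) -> list[tuple[float, int, int]]:
        """Contiguous runs of samples as ``(start_epoch, i0, i1)`` triples.

        ``i0:i1`` indexes into the sample arrays; chunk k > 0 starts at the
        end of gap k-1.
        """
        return chunk_table(self.start_epoch, self.n_samples, self.fs, self.gaps)

    @property
    def end_epoch(self) -> float:
        """Epoch just past the last sample."""
        t0, a, b = self.chunks()[-1]
        return t0 + (b - a) / self.fs

    def coverage(self) -> list[tuple[float, float]]:
        """Time intervals actually covered by samples."""
        return [(t0, t0 + (b - a) / self.fs) for (t0, a, b) in self.chunks()]

    def to_dataframe(self) -> pd.DataFrame:
        """Columnar debug view: epoch_s, ax_g, ay_g, az_g."""
        times = np.concatenate(
            [t0 + np.arange(b - a) / self.fs for (t0, a, b) in self.chunks()]
        ) if self.n_samples else np.empty(0)
        return pd.DataFrame(
            {"epoch_s": times, "ax_g": self.ax, "ay_g": self.ay, "az_g": self.az}
        )


def read_e4_acc(path, hand_label: str = "unknown") -> RawAccelRecording:
    """Read one E4 ACC CSV file into a calibrated recording.

    Raw counts are divided by 64 (1/64 g per count); non-integer numeric
    values are tolerated to support pre-calibrated exports.
    """
    with open(path) as fh:
        header_ts = fh.readline()
        header_fs = fh.readline()
        try:
            start_epoch = float(header_ts.strip().split(",")[0])
        except (ValueError, IndexError):
            raise FormatError(
                f"{path}: header row 1 is not a numeric Unix timestamp: {header_ts!r}"
            )
        try:
            fs = float(header_fs.strip().split(",")[0])
        except (ValueError, IndexError):
            raise FormatError(
                f"{path}: header row 2 is not a numeric sampling rate: {header_fs!r}"
            )
        if fs <= 0:
            raise FormatError(f"{path}: sampling rate must be positive, got {fs}")
        rows = []
        for lineno, line in enumerate(fh, start=3):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise FormatError(
                    f"{path}: row {lineno} has {len(parts)} columns, expected 3"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise FormatError(f"{path}: row {lineno} is not numeric: {line!r}")
    if not rows:
        raise EmptyRecordingError(f"{path}: no samples after the two header rows")
    counts = np.asarray(rows, dtype=float)
    g = counts / COUNTS_PER_G
    return RawAccelRecording(
        start_epoch=start_epoch,
        fs=fs,
        ax=g[:, 0],
        ay=g[:, 1],
        az=g[:, 2],
        hand_label=hand_label,
    )


def write_e4_acc(rec: RawAccelRecording, path) -> None:
    """Write a recording back to the E4 ACC dialect (counts of 1/64 g).

    Only writes gap-free recordings: the dialect has no way to express
    missing stretches, so multi-chunk recordings must be written per chunk.
    """
    if rec.gaps:
        raise ValueError("cannot write a recording with gaps to a single E4 file")
    counts = np.column_stack([rec.ax, rec.ay, rec.az]) * COUNTS_PER_G
    rounded = np.round(counts)
    integral = np.allclose(counts, rounded, atol=1e-9)
    with open(path, "w") as fh:
        fh.write(f"{rec.start_epoch:.6f}\n{rec.fs:.6f}\n")
        if integral:
            for x, y, z in rounded.astype(int):
                fh.write(f"{x},{y},{z}\n")
        else:
            for x, y, z in counts:
                fh.write(f"{x:.6f},{y:.6f},{z:.6f}\n")


def stitch(
    recordings: list[RawAccelRecording], max_gap_s: float = 0.0
) -> RawAccelRecording:
    """Concatenate per-file recordings of one hand into one stream.

    Inter-file intervals longer than ``max_gap_s`` become entries of the
    output ``gaps`` list; shorter ones are treated as device-clock jitter
    and the files as abutting.  Never fabricates samples: the output sample
    count is exactly the sum of the inputs'.
    """
    if not recordings:
        raise EmptyRecordingError("no recordings to stitch")
    recs = sorted(recordings, key=lambda r: r.start_epoch)
    fs = recs[0].fs
    hand = recs[0].hand_label
    for r in recs[1:]:
        if r.fs != fs:
            raise IncompatibilityError(f"mixed sampling rates: {fs} vs {r.fs}")
        if r.hand_label != hand:
            raise IncompatibilityError(f"mixed hand labels: {hand} vs {r.hand_label}")
    gaps: list[tuple[float, float]] = []
    for prev, nxt in zip(recs, recs[1:]):
        if nxt.start_epoch < prev.end_epoch - 0.5 / fs:
            raise OverlapError(
                f"recordings overlap: one ends at {prev.end_epoch}, "
                f"next starts at {nxt.start_epoch}"
            )
        interval = nxt.start_epoch - prev.end_epoch
        if interval > max_gap_s and interval > 0.5 / fs:
            gaps.append((prev.end_epoch, nxt.start_epoch))
    # carry over intra-file gaps of the inputs as well
    for r in recs:
        gaps.extend(r.gaps)
    gaps.sort()
    return RawAccelRecording(
        start_epoch=recs[0].start_epoch,
        fs=fs,
        ax=np.concatenate([r.ax for r in recs]),
        ay=np.concatenate([r.ay for r in recs]),
        az=np.concatenate([r.az for r in recs]),
        hand_label=hand,
        gaps=gaps,
    )


def slice_recording(rec: RawAccelRecording, t0: float, t1: float) -> RawAccelRecording:
    """Restrict a recording to samples with timestamps in ``[t0, t1)``.

    Gap metadata is clipped to the window.  Returns an empty recording
    (0 samples, start at ``t0``) if nothing falls inside.
    """
    parts_x, parts_y, parts_z = [], [], []
    chunk_spans: list[tuple[float, int]] = []
    fs = rec.fs
    for (tc, a, b) in rec.chunks():
        n = b - a
        i0 = int(np.ceil((t0 - tc) * fs - 1e-9))
        i1 = int(np.ceil((t1 - tc) * fs - 1e-9))
        i0, i1 = max(0, i0), min(n, i1)
        if i1 <= i0:
            continue
        parts_x.append(rec.ax[a + i0 : a + i1])
        parts_y.append(rec.ay[a + i0 : a + i1])
        parts_z.append(rec.az[a + i0 : a + i1])
        chunk_spans.append((tc + i0 / fs, i1 - i0))
    if not chunk_spans:
        return RawAccelRecording(
            start_epoch=t0, fs=fs, ax=np.empty(0), ay=np.empty(0), az=np.empty(0),
            hand_label=rec.hand_label,
        )
    gaps = []
    for (ts, n), (ts_next, _) in zip(chunk_spans, chunk_spans[1:]):
        gaps.append((ts + n / fs, ts_next))
    return RawAccelRecording(
        start_epoch=chunk_spans[0][0],
        fs=fs,
        ax=np.concatenate(parts_x),
        ay=np.concatenate(parts_y),
        az=np.concatenate(parts_z),
        hand_label=rec.hand_label,
        gaps=gaps,
    )


def count_samples_in(rec: RawAccelRecording, t0: float, t1: float) -> int:
    """Number of samples with timestamps in the closed interval ``[t0, t1]``."""
    total = 0
    fs = rec.fs
    for (tc, a, b) in rec.chunks():
        n = b - a
        i0 = int(np.ceil((t0 - tc) * fs - 1e-9))
        i1 = int(np.floor((t1 - tc) * fs + 1e-9)) + 1
        total += max(0, min(n, i1) - max(0, i0))
    return total
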