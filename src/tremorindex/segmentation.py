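"""Calendar-day segmentation and the daytime completeness exclusion rule.

Recordings are cut at local midnights into 24-hour segments
(00:00:00-23:59:59 wall clock).  A segment is kept only if *less than* half
of the samples expected in the daytime window 07:01:00-23:59:59 (61,139 s,
both bounds inclusive) are missing; nighttime samples are always retained so
a kept day yields a full 24-hour tremor overview.  Day boundaries are wall
clock, so the time zone is an explicit parameter; daylight-saving days use
their actual 23- or 25-hour length.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from zoneinfo import ZoneInfo

from .e4_io import RawAccelRecording, count_samples_in, slice_recording

DAYTIME_START = time(7, 1, 0)
DAYTIME_END = time(23, 59, 59)
#: seconds in [07:01:00, 23:59:59], both bounds inclusive of their sample
DAYTIME_SECONDS = 61_139


@dataclass
class DaySegment:
    """One local calendar day of data plus its daytime completeness.

    ``daytime_completeness`` is the fraction (0-1) of samples expected in the
    07:01-23:59 window that are actually present.
    """

    date: date
    recording: RawAccelRecording
    daytime_completeness: float


def _local_midnight_epoch(d: date, tz: ZoneInfo) -> float:
    return datetime.combine(d, time(0, 0), tzinfo=tz).timestamp()


def segment_days(rec: RawAccelRecording, tz: str | ZoneInfo) -> list[DaySegment]:
    """Cut a recording into local calendar-day segments.

    Every sample lands in exactly one segment; partial first/last days are
    returned as-is (exclusion is :func:`filter_segments`' job).  An empty
    recording yields an empty list.
    """
    if isinstance(tz, str):
        tz = ZoneInfo(tz)
    if rec.n_samples == 0:
        return []
    first_day = datetime.fromtimestamp(rec.start_epoch, tz).date()
    # subtract half a sample so a recording ending exactly at midnight does
    # not spawn an empty trailing day
    last_day = datetime.fromtimestamp(rec.end_epoch - 0.5 / rec.fs, tz).date()
    segments = []
    d = first_day
    while d <= last_day:
        t0 = _local_midnight_epoch(d, tz)
        t1 = _local_midnight_epoch(d + timedelta(days=1), tz)
        day_rec = slice_recording(rec, t0, t1)
        a = datetime.combine(d, DAYTIME_START, tzinfo=tz).timestamp()
        b = datetime.combine(d, DAYTIME_END, tzinfo=tz).timestamp()
        expected = rec.fs * (b - a)
        observed = count_samples_in(day_rec, a, b)
        completeness = min(1.0, observed / expected) if expected > 0 else 0.0
        if day_rec.n_samples > 0:
            segments.append(DaySegment(d, day_rec, completeness))
        d += timedelta(days=1)
    return segments


def filter_segments(
    segments: list[DaySegment], missing_threshold: float = 0.5
) -> list[DaySegment]:
    """Drop segments with at least ``missing_threshold`` daytime data missing.

    A segment survives iff ``daytime_completeness > 1 - missing_threshold``;
    at exactly 50% missing it is excluded.  Idempotent, order preserving.
    """
    if not 0 < missing_threshold <= 1:
        raise ValueError("missing_threshold must be in (0, 1]")
    keep = 1.0 - missing_threshold
    return [s for s in segments if s.daytime_completeness > keep]
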