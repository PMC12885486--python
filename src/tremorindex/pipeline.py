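"""End-to-end workflows: Mode I (frequency mapping) and Mode II (tracking).

Mode I compares the two hands of one participant: full quantification on
both wrists, per-frequency TI distributions on a shared bin grid, the
second-peak log distance D_f, separation flags c_f and their count C.
Mode II follows a single hand over time: the long-format TI table per ST
window plus per-day summaries, with no inter-hand statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .distribution_stats import shape_summary_frame
from .e4_io import RawAccelRecording
from .errors import EmptyDataError
from .hand_separation import SeparationResult, separate_hands
from .segmentation import DaySegment, filter_segments, segment_days
from .tremor_index import TISeries, ti_profile, ti_to_frame


def quantify_recording(
    rec: RawAccelRecording, config: RunConfig
) -> tuple[dict[int, TISeries], list[DaySegment]]:
    """Segment, filter, and compute the per-frequency TI profile."""
    segments = filter_segments(
        segment_days(rec, config.timezone), config.missing_threshold
    )
    profile = ti_profile(
        rec,
        segments,
        frequencies=config.frequency_set,
        st_minutes=config.st_minutes,
        beta=config.beta,
        tz=config.timezone,
        wavelet=config.wavelet,
        depth=config.depth_j,
    )
    return profile, segments


def pooled_valid_ti(profile: dict[int, TISeries]) -> dict[int, np.ndarray]:
    """Pool valid TI values across all kept days, per frequency."""
    return {f: s.valid_values for f, s in profile.items()}


@dataclass
class Mode1Result:
    """Frequency-mapping report for one participant."""

    ti_table: pd.DataFrame
    shape_summary: pd.DataFrame
    separation: SeparationResult
    n_days: dict[str, int]


def run_mode1(
    rec_t: RawAccelRecording, rec_nt: RawAccelRecording, config: RunConfig
) -> Mode1Result:
    """Two-hand pipeline: TI profiles, distribution shapes, D_f/c_f/C."""
    prof_t, seg_t = quantify_recording(rec_t, config)
    prof_nt, seg_nt = quantify_recording(rec_nt, config)
    if not seg_t or not seg_nt:
        raise EmptyDataError(
            "mode I needs at least one kept day segment per hand "
            f"(T: {len(seg_t)}, nT: {len(seg_nt)})"
        )
    ti_t = pooled_valid_ti(prof_t)
    ti_nt = pooled_valid_ti(prof_nt)
    table = pd.concat(
        [
            ti_to_frame(prof_t, "T", config.timezone),
            ti_to_frame(prof_nt, "nT", config.timezone),
        ],
        ignore_index=True,
    )
    summary = shape_summary_frame({"T": ti_t, "nT": ti_nt}, config.nbins)
    separation = separate_hands(
        ti_t, ti_nt, nbins=config.nbins, rule=config.separation_rule
    )
    return Mode1Result(
        ti_table=table,
        shape_summary=summary,
        separation=separation,
        n_days={"T": len(seg_t), "nT": len(seg_nt)},
    )


@dataclass
class Mode2Result:
    """Longitudinal TI report for one hand."""

    ti_table: pd.DataFrame
    day_summary: pd.DataFrame
    n_days: int

    @property
    def empty(self) -> bool:
        return self.n_days == 0


def run_mode2(rec: RawAccelRecording, config: RunConfig) -> Mode2Result:
    """Single-hand pipeline: long TI table and per-day summaries."""
    profile, segments = quantify_recording(rec, config)
    table = ti_to_frame(profile, rec.hand_label, config.timezone)
    if table.empty:
        day_summary = pd.DataFrame(
            columns=["date", "f_hz", "n_valid", "ti_mean", "ti_median", "ti_max"]
        )
    else:
        valid = table[table["valid"]]
        day_summary = (
            valid.groupby(["date", "f_hz"])["ti_tiu"]
            .agg(n_valid="size", ti_mean="mean", ti_median="median", ti_max="max")
            .reset_index()
        )
    return Mode2Result(ti_table=table, day_summary=day_summary, n_days=len(segments))


def separation_frame(
    results: dict[str, SeparationResult], loads: dict[str, int], freq_count: int
) -> pd.DataFrame:
    """Per-participant long table of D_f, c_f, C, L and normalized scores."""
    rows = []
    for pid, sep in results.items():
        load = loads.get(pid)
        for f in sorted(sep.d_f):
            rows.append(
                {
                    "participant_id": pid,
                    "f_hz": f,
                    "D_f": sep.d_f[f],
                    "bin_T": sep.bin_t[f],
                    "bin_nT": sep.bin_nt[f],
                    "c_f": sep.c_f[f],
                    "C": sep.C,
                    "L": load,
                    "C_norm": 10.0 * sep.C / freq_count,
                    "L_norm": (10.0 * load / 36.0) if load is not None else np.nan,
                    "threshold_rule": sep.threshold_rule,
                }
            )
    return pd.DataFrame(rows)
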