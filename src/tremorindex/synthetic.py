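"""Seedable synthetic two-hand accelerometer recordings with known tremor.

No public recordings exist for this kind of free-living wrist study, so the
generator emulates the measurement chain end to end: a gravity-orientation
baseline on the Oz axis, a slow 0.1-2 Hz daily-activity process, tremor
bursts in the 3-12 Hz band gated by a two-state semi-Markov (exponential
burst/quiet) process with controllable duty cycle, white sensor noise,
1/64 g quantization, 32 Hz sampling, optional data gaps, and reduced
activity/tremor at night.  Tremor frequency jitters within +/-0.3 Hz inside
a burst, mimicking the peak inconsistency of real tremor.  Ground-truth
burst intervals are returned alongside every recording.

The cohort generator reproduces the study design: each participant wears the
device on the most affected hand for a block of days and then on the other
hand, with clinical tremor-item intensities assigned monotonically with the
injected tremor breadth and amplitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path
from zoneinfo import ZoneInfo

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .e4_io import RawAccelRecording, stitch, write_e4_acc
from .hand_separation import ClinicalScores

DEVICE_FS = 32.0
QUANTUM_G = 1.0 / 64.0


@dataclass
class TremorComponent:
    """One injected tremor oscillation.

    ``duty`` is the long-run fraction of time spent bursting;
    ``mean_burst_s`` the mean length of one burst.
    """

    freq_hz: float
    amplitude_g: float
    duty: float = 0.1
    mean_burst_s: float = 180.0
    #: gamma shape of burst/quiet durations; 1 = exponential (memoryless),
    #: larger values give more regular episode lengths at the same means
    regularity: float = 1.0

    def __post_init__(self) -> None:
        if not 3.0 <= self.freq_hz <= 12.0:
            raise ValueError("tremor frequency must lie in [3, 12] Hz")
        if not 0.0 <= self.duty <= 1.0:
            raise ValueError("duty cycle must lie in [0, 1]")
        if self.amplitude_g < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass
class HandProfile:
    """Generative parameters for one hand."""

    tremor_components: list[TremorComponent] = field(default_factory=list)
    activity_level_g: float = 0.05
    noise_sd_g: float = 0.01
    baseline_g: float = 0.35
    #: gate all components with one episode schedule (that of the first
    #: component) instead of independent per-component burst processes —
    #: a tremor episode then expresses the hand's whole spectrum at once
    shared_episodes: bool = False


@dataclass
class Burst:
    """Ground-truth burst interval [t0, t1) with its realized frequency."""

    t0: float
    t1: float
    freq_hz: float


FREQ_JITTER_HZ = 0.3
NIGHT_FACTOR = 0.25  # activity amplitude and burst survival scaling, 00-07h
RAMP_S = 0.5


def _burst_intervals(
    comp: TremorComponent, duration: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Alternating gamma-duration quiet/burst process over [0, duration)."""
    if comp.duty <= 0 or comp.amplitude_g == 0:
        return []
    if comp.duty >= 1:
        return [(0.0, duration)]
    k = comp.regularity
    mean_quiet = comp.mean_burst_s * (1 - comp.duty) / comp.duty
    draw = lambda mean: rng.gamma(k, mean / k)
    out = []
    t = draw(mean_quiet)  # start quiet
    while t < duration:
        b = draw(comp.mean_burst_s)
        out.append((t, min(t + b, duration)))
        t += b + draw(mean_quiet)
    return out


def _activity(n: int, fs: float, level_g: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited 0.1-2 Hz daily-motion process with RMS ``level_g``."""
    if level_g <= 0 or n < 64:
        return np.zeros(n)
    sos = butter(4, [0.1, 2.0], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x * x))
    return x * (level_g / rms) if rms > 0 else x


def _night_mask(
    n: int, fs: float, start_epoch: float, tz: ZoneInfo
) -> np.ndarray:
    """True where the local wall-clock hour is in [00:00, 07:00).

    Uses the UTC offset at the recording start (sub-day recordings; a DST
    step mid-recording shifts the mask by an hour, which is irrelevant for
    the statistics the generator serves).
    """
    offset = datetime.fromtimestamp(start_epoch, tz).utcoffset().total_seconds()
    tod = (start_epoch + offset + np.arange(n) / fs) % 86400.0
    return tod < 7 * 3600.0


def simulate_hand(
    profile: HandProfile,
    start_epoch: float,
    duration_s: float,
    hand_label: str = "T",
    fs: float = DEVICE_FS,
    seed: int | np.random.Generator = 0,
    tz: str | ZoneInfo = "UTC",
    gap_schedule: list[tuple[float, float]] | None = None,
    night_factor: float = NIGHT_FACTOR,
) -> tuple[RawAccelRecording, list[Burst]]:
    """Simulate one hand's recording; returns (recording, ground-truth bursts).

    Oz = baseline + slow activity + gated tremor + Gaussian noise, quantized
    to 1/64 g.  Bursts whose start falls at night survive with probability
    ``night_factor``, and the activity amplitude is scaled by it at night.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(tz, str):
        tz = ZoneInfo(tz)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    night = _night_mask(n, fs, start_epoch, tz)
    act_scale = np.where(night, night_factor, 1.0)
    az = profile.baseline_g + _activity(n, fs, profile.activity_level_g, rng) * act_scale
    bursts: list[Burst] = []
    shared = (
        _burst_intervals(profile.tremor_components[0], duration_s, rng)
        if profile.shared_episodes and profile.tremor_components
        else None
    )
    for comp in profile.tremor_components:
        intervals = shared if shared is not None else _burst_intervals(
            comp, duration_s, rng
        )
        for (b0, b1) in intervals:
            if night[min(n - 1, int(b0 * fs))] and rng.random() > night_factor:
                continue
            fq = comp.freq_hz + rng.uniform(-FREQ_JITTER_HZ, FREQ_JITTER_HZ)
            phase = rng.uniform(0, 2 * np.pi)
            i0, i1 = int(np.ceil(b0 * fs)), min(n, int(np.ceil(b1 * fs)))
            if i1 <= i0:
                continue
            tt = t[i0:i1]
            env = np.minimum(1.0, np.minimum(tt - b0, b1 - tt) / RAMP_S)
            az[i0:i1] += comp.amplitude_g * np.clip(env, 0, 1) * np.sin(
                2 * np.pi * fq * (tt - b0) + phase
            )
            bursts.append(Burst(start_epoch + b0, start_epoch + b1, fq))
    az += profile.noise_sd_g * rng.standard_normal(n)
    ax = profile.noise_sd_g * rng.standard_normal(n)
    ay = profile.noise_sd_g * rng.standard_normal(n)
    q = lambda v: np.round(v / QUANTUM_G) * QUANTUM_G
    rec = RawAccelRecording(
        start_epoch=start_epoch, fs=fs,
        ax=q(ax), ay=q(ay), az=q(az), hand_label=hand_label,
    )
    if gap_schedule:
        rec = _cut_gaps(rec, gap_schedule)
    return rec, bursts


def _cut_gaps(
    rec: RawAccelRecording, gaps: list[tuple[float, float]]
) -> RawAccelRecording:
    """Remove samples inside the given epoch intervals, recording them as gaps."""
    keep = np.ones(rec.n_samples, dtype=bool)
    times = rec.start_epoch + np.arange(rec.n_samples) / rec.fs
    clipped = []
    for (g0, g1) in sorted(gaps):
        m = (times >= g0) & (times < g1)
        if m.any():
            idx = np.flatnonzero(m)
            clipped.append((times[idx[0]], times[idx[-1]] + 1 / rec.fs))
            keep &= ~m
    return RawAccelRecording(
        start_epoch=rec.start_epoch, fs=rec.fs,
        ax=rec.ax[keep], ay=rec.ay[keep], az=rec.az[keep],
        hand_label=rec.hand_label, gaps=clipped,
    )


# --- cohort design -----------------------------------------------------------

#: order in which frequencies are added as designed tremor breadth grows;
#: contiguous from the classic rest-tremor range upward, so each increment
#: extends the separated band rather than scattering it
FREQ_POOL = (5, 6, 7, 8, 9, 10, 11, 12, 4, 3)

#: (rest, postural, kinetic) item intensities for breadth 0..6, monotone per
#: item in breadth; rest tremor leads, as is typical for PD cohorts
_CLINICAL_BY_BREADTH = [
    (0, 0, 0),
    (4, 4, 0),
    (4, 4, 1),
    (4, 4, 4),
    (4, 4, 4),
    (4, 4, 4),
    (4, 4, 4),
]

#: tremor amplitude (g) for breadth 1..6 (index 0 unused); grows with
#: breadth so symptom load reflects both extent and intensity
_AMP_BY_BREADTH = [0.0, 0.03, 0.06, 0.12, 0.16, 0.2, 0.25]


def clinical_for_breadth(breadth: int) -> ClinicalScores:
    rest, postural, kinetic = _CLINICAL_BY_BREADTH[min(breadth, 6)]
    return ClinicalScores(postural=postural, kinetic=kinetic, rest=rest)


@dataclass
class CohortData:
    """Synthetic cohort: recordings, clinical scores, and ground truth."""

    recordings: dict[str, dict[str, RawAccelRecording]]
    clinical: dict[str, ClinicalScores]  # affected (T) hand scores
    truth: dict[str, dict]
    tz: str


def simulate_cohort(
    n: int = 7,
    seed: int = 0,
    breadths: list[int] | None = None,
    days_per_hand: int = 2,
    hours_per_day: float = 12.0,
    start_hour: int = 7,
    amplitude_g: float | None = None,
    duty: float = 0.5,
    mean_burst_s: float = 2700.0,
    episode_regularity: float = 3.0,
    activity_level_g: float = 0.05,
    noise_sd_g: float = 0.01,
    tz: str = "UTC",
    start_date: tuple[int, int, int] = (2023, 5, 1),
) -> CohortData:
    """Simulate ``n`` participants with designed tremor breadths.

    Participant i carries tremor at the first ``breadths[i]`` frequencies of
    :data:`FREQ_POOL` in the most-affected hand only; the other hand gets
    activity and noise but no tremor.  Sustained episodes (mean 45 min,
    long relative to the 15-min ST window, as in medication OFF periods)
    make the affected hand's TI distribution bimodal, so the second-peak
    separation has a ground truth to recover.  Unless ``amplitude_g`` is
    given, amplitude grows with breadth (:data:`_AMP_BY_BREADTH`), so the
    designed symptom load reflects both tremor extent and intensity.  Wear
    is asynchronous: T-hand days first, then nT-hand days, as in a
    switch-at-midpoint protocol.
    """
    if n < 3:
        raise ValueError("cohort needs at least 3 participants")
    if breadths is None:
        breadths = [min(3, (i + 1) // 2) for i in range(n)]
    if len(breadths) != n:
        raise ValueError("breadths must have one entry per participant")
    zone = ZoneInfo(tz)
    rng = np.random.default_rng(seed)
    recordings: dict[str, dict[str, RawAccelRecording]] = {}
    clinical: dict[str, ClinicalScores] = {}
    truth: dict[str, dict] = {}
    day0 = datetime.combine(
        datetime(*start_date).date(), time(start_hour, 0), tzinfo=zone
    )
    for i, b in enumerate(breadths):
        pid = f"P{i + 1}"
        freqs = list(FREQ_POOL[:b])
        amp = amplitude_g if amplitude_g is not None else _AMP_BY_BREADTH[min(b, 6)]
        t_profile = HandProfile(
            tremor_components=[
                TremorComponent(f, amp, duty, mean_burst_s, episode_regularity)
                for f in freqs
            ],
            activity_level_g=activity_level_g,
            noise_sd_g=noise_sd_g,
            shared_episodes=True,
        )
        nt_profile = HandProfile(
            activity_level_g=activity_level_g, noise_sd_g=noise_sd_g
        )
        per_hand: dict[str, RawAccelRecording] = {}
        all_bursts: list[Burst] = []
        for h_idx, (hand, prof) in enumerate([("T", t_profile), ("nT", nt_profile)]):
            day_recs = []
            for d in range(days_per_hand):
                start = day0 + timedelta(days=h_idx * days_per_hand + d)
                rec, bursts = simulate_hand(
                    prof,
                    start_epoch=start.timestamp(),
                    duration_s=hours_per_day * 3600.0,
                    hand_label=hand,
                    seed=rng,
                    tz=zone,
                )
                day_recs.append(rec)
                all_bursts.extend(bursts)
            per_hand[hand] = stitch(day_recs) if len(day_recs) > 1 else day_recs[0]
        recordings[pid] = per_hand
        clinical[pid] = clinical_for_breadth(b)
        truth[pid] = {
            "breadth": int(b),
            "frequencies": freqs,
            "expected_C": int(b),
            "bursts": [(bu.t0, bu.t1, bu.freq_hz) for bu in all_bursts],
        }
    return CohortData(recordings=recordings, clinical=clinical, truth=truth, tz=tz)


def write_cohort(cohort: CohortData, out_dir) -> None:
    """Write a cohort as E4-format CSVs + clinical.csv + ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pid, hands in cohort.recordings.items():
        for hand, rec in hands.items():
            d = out / pid / hand
            d.mkdir(parents=True, exist_ok=True)
            for k, (tc, a, b) in enumerate(rec.chunks()):
                piece = RawAccelRecording(
                    start_epoch=tc, fs=rec.fs,
                    ax=rec.ax[a:b], ay=rec.ay[a:b], az=rec.az[a:b],
                    hand_label=hand,
                )
                write_e4_acc(piece, d / f"ACC_{k:03d}.csv")
    with open(out / "clinical.csv", "w") as fh:
        fh.write("participant_id,hand,postural_0_4,kinetic_0_4,rest_0_4\n")
        for pid, sc in cohort.clinical.items():
            fh.write(f"{pid},T,{sc.postural},{sc.kinetic},{sc.rest}\n")
    truth = {
        pid: {k: v for k, v in entry.items() if k != "bursts"}
        for pid, entry in cohort.truth.items()
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
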