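"""Quantify tremor over one synthetic day of wrist accelerometry.

Simulates a 25-hour recording with 5 Hz tremor episodes, cuts it into
calendar days, applies the daytime completeness rule, and prints the
Tremor Index (TI) profile of the one kept day.  TI is the energy of the
wavelet level at each frequency per 15-minute window, in tiu
(1 tiu = 100 mrad^2 per window): quiet windows sit near zero, windows
containing tremor episodes stand out by orders of magnitude.
"""

from datetime import datetime, timezone

import numpy as np

from tremorindex import (
    HandProfile,
    TremorComponent,
    filter_segments,
    segment_days,
    simulate_hand,
    ti_profile,
)

start = datetime(2023, 5, 1, 23, 30, tzinfo=timezone.utc).timestamp()
profile = HandProfile(
    tremor_components=[TremorComponent(freq_hz=5, amplitude_g=0.1)]
)
recording, bursts = simulate_hand(profile, start, 25 * 3600, seed=7)
print(f"simulated {recording.n_samples} samples at {recording.fs:g} Hz, "
      f"{len(bursts)} tremor bursts injected at ~5 Hz")

segments = segment_days(recording, "UTC")
kept = filter_segments(segments)
print(f"{len(segments)} calendar days -> {len(kept)} kept by the "
      f"daytime completeness rule (>=50% of 07:01-23:59 present)")

ti = ti_profile(recording, kept, frequencies=range(3, 13))
print("\nf_hz  valid/96  mean_TI_tiu  max_TI_tiu")
for f, series in sorted(ti.items()):
    v = series.valid_values
    print(f"{f:4d}  {len(v):5d}     {np.mean(v):11.1f} {np.max(v):11.1f}")
print("\nThe 5 Hz level (and its neighbours, via band overlap) carries the"
      "\ninjected tremor energy; far bands stay near the noise floor.")
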