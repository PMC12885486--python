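"""Separated-frequency count vs clinical symptom load across a cohort.

Simulates a seven-participant cohort with designed tremor breadths, runs
the two-hand pipeline per participant, and correlates the recovered count
of separated frequencies C (normalized to 0-10) with the clinical tremor
symptom load L = (present types) x (summed MDS-UPDRS intensities),
also normalized to 0-10.  Prints Pearson r with the paired-difference
verification (95% CI and t-test of the C-L differences).
"""

import warnings

from tremorindex import (
    RunConfig,
    associate,
    run_mode1,
    simulate_cohort,
    symptom_load,
)

warnings.filterwarnings("ignore")

cohort = simulate_cohort(n=7, seed=42)
config = RunConfig()

print("pid  breadth  L   C")
c_list, l_list = [], []
for pid in sorted(cohort.recordings, key=lambda p: int(p[1:])):
    res = run_mode1(cohort.recordings[pid]["T"],
                    cohort.recordings[pid]["nT"], config)
    load = symptom_load(cohort.clinical[pid])
    c_list.append(res.separation.C)
    l_list.append(load)
    print(f"{pid:3s}  {cohort.truth[pid]['breadth']:7d} {load:3d} "
          f"{res.separation.C:3d}")

stats = associate(c_list, l_list, freq_count=10)
print(f"\nPearson r = {stats.pearson_r:.3f} (p = {stats.pearson_p:.4f})")
print(f"mean C-L difference (0-10 scale) = {stats.mean_diff:.3f}, "
      f"95% CI [{stats.ci95[0]:.3f}, {stats.ci95[1]:.3f}], "
      f"paired t-test p = {stats.ttest_p:.3f}")
print("\nA high r with a CI covering zero mirrors the intended use: the"
      "\nnumber of separated TI frequencies tracks clinical tremor load.")
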