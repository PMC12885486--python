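"""Mode I frequency mapping: compare a participant's two hands.

Simulates one participant with sustained tremor episodes at 5 and 6 Hz in
the most affected hand (T) only, runs the full two-hand pipeline, and
prints the per-frequency separation: the second-peak log distance D_f, the
separation flag c_f, and the count C of separated frequencies.  Band
overlap makes neighbouring frequencies separate too, which is the method's
stated resolution limit.
"""

from tremorindex import RunConfig, run_mode1, simulate_cohort

# participant P4 of the designed cohort has breadth 2: tremor at 5 and 6 Hz
cohort = simulate_cohort(n=7, seed=3)
rec_t = cohort.recordings["P4"]["T"]
rec_nt = cohort.recordings["P4"]["nT"]
print(f"injected frequencies: {cohort.truth['P4']['frequencies']}")

result = run_mode1(rec_t, rec_nt, RunConfig())
print(f"kept days: T={result.n_days['T']}, nT={result.n_days['nT']}")
print(f"\nf_hz    D_f  bin_T_tiu  bin_nT_tiu  c_f")
sep = result.separation
for f in sorted(sep.d_f):
    print(f"{f:4d} {sep.d_f[f]:6.2f} {sep.bin_t[f]:10.1f} "
          f"{sep.bin_nt[f]:11.3f}  {sep.c_f[f]}")
print(f"\nC = {sep.C} separated frequencies ({sep.threshold_rule})")
print("D_f > 0 means the tremor hand's second distribution peak sits at"
      "\nhigher TI; c_f flags peaks at least 30% of the max TI apart.")
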