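# Methods

This note records the model, the numerical choices, and the synthetic
study design behind `tremorindex`, at the level of detail a maintainer or
reviewer needs to judge what the package's tests do and do not show.

## Signal model and assumptions

The pipeline assumes a wrist-worn 3-axis accelerometer sampling at a
nominally constant rate (32 Hz by default), calibrated by a fixed scale of
1/64 g per count. Only the Oz axis is used: tremor-related
flexion/extension and rolling project onto it, while walking arm swing and
most manual activities live mainly in the other two axes. The elevation
angle `theta = arctan(a_z / 1)` treats the forearm as a unit lever, which
standardizes the angle across people at the cost of absolute amplitude
comparability between participants — the method is explicitly
within-person (hand vs hand, day vs day).

Timestamps are Unix epoch internally; wall-clock conversions happen only
at day segmentation, so the time zone is a required parameter. No clock
drift correction is applied across multi-file sessions; files are stitched
with their gaps kept as first-class metadata and no sample is ever
interpolated, because the day-exclusion rule needs true missingness.

## Frequency assignment

A wavelet detail at level j of a signal sampled at fs occupies the dyadic
band (fs/2^{j+1}, fs/2^j]. To give every integer frequency f in 3–12 Hz
its own level, the elevation series is resampled per frequency to
fs_f = 8f/3 Hz (an exact small rational of 32 Hz: fs_f/32 = f/12) and the
*first* detail band (fs_f/4, fs_f/2] = (2f/3, 4f/3] is taken; its centre
3fs_f/8 equals f. Resampling uses polyphase anti-aliased filtering
(`scipy.signal.resample_poly`), chunk by chunk, never across a gap.

These bands overlap heavily by construction (the f = 5 band is
(3.3, 6.7] Hz), so a pure tone at f raises the levels at f±1 and beyond.
This bleed-through is intrinsic to the dyadic design; the tests therefore
require only that the argmax level is within ±1 of a tone's frequency, and
the separation analysis treats the flagged set as a band, not a line.

## The transform

The decomposition is a shift-invariant (maximal-overlap) Daubechies
transform in orthonormal normalization, implemented as circular à-trous
filtering with reflection padding at chunk boundaries (`_modwt.py`). It
matches `pywt.swt(..., norm=True)` / `pywt.mra` sample for sample — the
test suite asserts exact agreement — but reconstructs components
*selectively*: the tremor index needs only the first detail, and
reconstructing all J+1 components the way a generic MRA routine does costs
an order of magnitude more on multi-day recordings. Defaults: `db4`
(support 8; a compromise between band selectivity and transient length,
configurable db2–db10) at depth J = 4, so the smooth holds content below
fs_f/32 and absorbs posture and daily motion.

Properties guaranteed by construction and checked by tests: additivity
(details + smooth = input to ~1e−15), coefficient energy conservation
(orthonormal filters), and same-length levels so ST windows index
uniformly.

Edge handling: the first and last `3L` samples of each chunk's level
(L = filter length; 24 samples for db4) are flagged invalid. The composite
analysis+synthesis kernel of the first detail spans 2L−1 samples and the
polyphase resampler adds a boundary transient of about 10 output samples;
3L covers both with margin. Chunks shorter than the decomposition minimum
(L−1)·2^J samples are skipped and become gaps.

## Tremor index and windowing

TI_f = beta · Σ theta_f(i)² over non-overlapping windows of
q = ST·60·fs_f samples (q = 2400·f for the 15-minute default — always an
integer). beta = 1e4 converts rad² to the declared unit
(1 tiu = 100 mrad²/ST: 10⁶ mrad²/rad² ÷ 100). Windows are aligned to
wall-clock multiples of ST (quarter hours), matching on-the-hour and
half-past medication schedules; alignment is a package decision, since
only the window length is fixed by the unit definition. A window is valid
only if all q samples exist inside one contiguous chunk and none is
edge-flagged — partial windows are never scaled up, because the fixed-q
sum would otherwise deflate silently.

## Day segmentation

Days are local calendar days (00:00:00–23:59:59); daylight-saving days use
their true 23- or 25-hour length. The daytime window is
[07:01:00, 23:59:59], i.e. 61,139 seconds, and a day is dropped when at
least 50% of fs × 61,139 expected daytime samples are missing (the
boundary case of exactly 50% missing is excluded). Nights are retained, so
a kept day yields a full 96-window circadian profile.

## Distribution statistics and hand separation

Pooled valid TI values per hand × frequency are binned into λ = 20 linear
bins. Each hand's density is binned over its **own** [0, max] range: a
grid shared across hands (scaled by the tremor hand's maximum) collapses a
quiet hand's entire distribution into one bin and leaves no second peak to
locate, which would make the statistic undefined exactly in the cases of
interest. The separation threshold still refers to the pooled maximum TI
at f across both hands, which keeps the criterion symmetric.

The second-highest-probability bin is the tremor mode's location (the
tallest bin is the rest mode near zero); ties break toward lower TI.
D_f = log10(bin_T) − log10(bin_nT) is reported on the log scale.
Flagging by comparing the log distance itself against 0.3 × max TI_f
would mix scales; the default rule keeps dimensional consistency by
thresholding the linear peak distance (bin_T − bin_nT ≥ 0.3 · max TI_f),
and the literal log-scale rule remains selectable, with the applied rule
recorded in every result.

Kurtosis is Pearson (normal = 3) and skewness the standardized third
moment, both bias-uncorrected, fixed for determinism. The log–log tail fit
is OLS of log10 probability on log10 bin centre with empty bins dropped.
C and L are normalized to 0–10 by theoretical maxima (|frequency set| and
36) rather than observed maxima, so the correlation does not depend on a
sample's extremes; Pearson r, the mean C−L difference with its 95%
t-interval, and a paired t-test are computed on the normalized scale.

## Synthetic data: what it emulates, and what not

`simulate_hand` builds Oz as: gravity baseline (0.35 g) + band-limited
0.1–2 Hz activity process (RMS 0.05 g by default) + tremor oscillations
gated by a two-state burst/quiet renewal process + white noise
(SD 0.01 g), quantized to 1/64 g. Burst and quiet durations are
gamma-distributed with a `regularity` shape parameter (default 1 =
exponential, i.e. a memoryless semi-Markov gate); tremor frequency jitters
±0.3 Hz per episode; nights (00–07 local) scale activity and thin bursts
to 25%. Defaults for a single bursty hand: duty 0.1, mean burst 180 s —
intermittent, minutes-long episodes.

The cohort generator reproduces a switch-at-midpoint protocol
(most-affected hand first, then the other) with designed tremor breadths.
Design choices, calibrated once on the generator before the acceptance
suite was frozen:

- **Sustained episodes** (mean 45 min ≫ the 15-min window, duty 0.5,
  regularity 3) make the affected hand's TI distribution bimodal so the
  second-peak statistic has a recoverable target; exponential durations
  with independent per-component gates occasionally produce days with
  almost no expressed tremor, a generator artifact rather than a property
  of the method, hence the shared episode gate and the regularity shape.
- Band overlap flags roughly ±2 neighbours per injected frequency, so the
  resolvable values of C at this scale are coarse (≈ 0, 4–5, 8, 9). The
  default design therefore uses paired breadths [0,1,1,2,2,3,3] over the
  contiguous pool (5, 6, 7, …), an amplitude ladder (0.03/0.06/0.12 g)
  growing with breadth, and clinical loads L = 0/16/27/36 that are
  monotone in the injected severity and approximately affine in the
  achievable E[C].
- Problem sizes are scaled-down study conditions chosen by the package:
  2 days × 12 h per hand for cohorts, one 12.5 h day for shape-statistic
  replicates.

The generator does **not** model limb biomechanics, medication
pharmacokinetics, tremor-activity interaction, sensor clock drift, or
non-white noise. Passing tests therefore demonstrate that the pipeline
recovers what this generative model encodes — band-limited intermittent
oscillations against slow motion and noise — not that it is clinically
valid on real recordings.

## Numerical details and degenerate inputs

- Window indices are computed as `round((t_window − t_chunk)·fs_f)`;
  window starts are exact multiples of the ST and chunk starts lie on the
  device sample grid, so the rounding is exact in practice.
- Histogram upper edges include the maximum value; an all-zero TI set
  bins into a single occupied bin over a unit span.
- Second peaks need ≥2 occupied bins; frequencies where either hand is
  degenerate are excluded from C with a warning rather than guessed.
- `associate` refuses zero-variance inputs; with identical normalized
  lists the paired t-test is reported as p = 1 with a degenerate CI.
- All randomness flows through `numpy.random.Generator` seeds; same seed,
  same bits.

## Known limitations

- The elevation proxy cannot separate pronation/supination from
  flexion/extension and ignores Ox/Oy tremor components.
- Dyadic band overlap limits frequency resolution to roughly ±1–2 Hz;
  C saturates once injected bands cover the 3–12 Hz range.
- The second-peak statistic needs enough valid windows per hand
  (≳40) for a stable 20-bin histogram; single short days are noisy.
- Between-participant TI amplitudes are not comparable by design
  (unit forearm length); only within-person contrasts are meaningful.
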