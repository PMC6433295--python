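# Methods

This note documents the models, estimators and numerical choices behind
`pafpipe`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## The scientific model

The working hypothesis is that the alpha cycle (8–13 Hz, cycle length
`1000/f` ≈ 77–125 ms) gates the temporal window over which two briefly
separated stimulus frames are integrated. Two observable consequences are
implemented and tested:

- **Between subjects** — the transition IFI threshold (the interframe
  interval at which element-motion and group-motion reports are equally
  likely) increases with the subject's alpha cycle length; equivalently it
  correlates negatively with peak alpha frequency. A gating account further
  predicts the threshold-on-cycle-length regression slope to be 1.
- **Within subjects** — trial-to-trial variation in prestimulus alpha
  frequency predicts the percept (faster alpha → group motion), and trials
  whose PAF-based prediction matches the later report (*efficient
  inference*) carry percept-like neural patterns already before the second
  frame, detectable by temporal-generalization decoding.

## Psychometric model

`P(GM | IFI) = 1/(1 + exp(−(IFI − a)/b))`, fitted by binomial maximum
likelihood on trial-level responses (a GLM with logit link), not least
squares on proportions — well defined under unequal per-IFI trial counts.
The threshold is `a = −β₀/β₁` exactly, so the fitted curve crosses 0.5 at
the reported threshold to machine precision. R² is computed on the seven
per-IFI observed proportions against the fitted values, matching how fit
quality is conventionally summarized for psychometric curves. An optional
lapse parameter exists in the observer *simulator* but the fitted function
has none (the default analysis model). Fits are flagged non-identifiable
when all responses agree, when the curve is flat, or when the threshold
falls outside the tested IFI range.

Cleaning rules and their order: omissions first (they have no RT), then
per-condition RT outliers at strictly more than 3 SD from the mean, then
explicit trials with percept-incongruent reports. A zero-SD RT distribution
removes nothing (|x − mean| > 0 is false). Cleaning statistics are computed
once, not iterated; on realistic RT distributions a second pass removes
nothing, which the tests verify on simulated data.

## Instantaneous-frequency estimator

The estimator is the phase-derivative ("frequency sliding") method:

1. restrict to the prestimulus window and **mirror-pad** (append the
   time-reversed epoch) so filter edge artifacts fall in the padded half;
2. **band-pass** with a zero-phase plateau filter;
3. take the analytic signal (Hilbert transform); amplitude = magnitude,
   power = amplitude²;
4. differentiate the unwrapped phase and scale by `fs/2π` to Hz (the final
   sample repeats the last difference, the first is a forward difference);
5. median-filter the raw derivative with 10 window lengths linearly spaced
   10–400 ms (rounded to odd sample counts ≥ 3) and take the pointwise
   median of the 10 versions.

The estimate depends only on phase, hence is invariant to per-trial
amplitude scaling (verified to 1e−9 relative); samples with exactly zero
amplitude have undefined phase and are returned as NaN. Interior accuracy
on a pure tone is < 0.01 Hz and on an 8→13 Hz linear chirp < 0.3 Hz RMSE
("interior" = more than 400 ms, the largest median window, from either
epoch edge).

**Filter realization.** The plateau band-pass is applied in the frequency
domain: the DFT is multiplied by a trapezoidal amplitude response — unity
over the band, raised-cosine transition zones spanning 15% of each band
edge (6.8–8 and 13–14.95 Hz), zero beyond. The impulse response is real
and time-symmetric, so the filter is exactly zero-phase with unit passband
gain and total stopband rejection on the DFT grid. A least-squares FIR
kernel short enough to convolve with a 1.6 s mirrored epoch (≤ 5 alpha
cycles) cannot simultaneously hold the passband within 1% and the stopband
below −20 dB at these transition widths, which is why the frequency-domain
realization is used.

**Mirror-junction caveat.** Mirroring reflects the samples, so a generic
oscillation has a derivative kink at the junction; the analytic-signal
ripple from that kink biases the frequency estimate near the junction
(≈ ±100 ms) and at the ~5×10⁻³ relative level further in. Analysis windows
therefore exclude the 200 ms nearest the stimulus onset; padding is exactly
transparent only for signals symmetric about the reflection axis.

## Synthetic cohorts

`SimConfig` defines the study conditions: 17 subjects, 64 channels at
160 Hz (intracranial variant: 500 Hz), epochs −800…+1000 ms around frame 1,
80 bistable trials per percept. Per trial the generator sums:

- a posterior-weighted alpha oscillator (posterior channels weight 1.0,
  distant channels 0.2, smooth Gaussian falloff) at a constant per-trial
  frequency `f = peak + 0.3·[GM] + N(0, 0.15)` Hz, clipped to the band,
  with random initial phase (a linear drift option exists, off by default);
- 1/f background noise (white spectra shaped by `1/f`, exponent 1.0),
  scaled so posterior alpha RMS / noise SD equals the configured SNR
  (default 1.0);
- after frame-2 onset (IFI + 30 ms frame duration), a percept-specific
  random spatial pattern under a 300-ms raised-cosine envelope. Patterns
  are normalized to unit per-channel RMS so `evoked_effect` (default 1.0)
  is the per-channel response amplitude relative to alpha regardless of
  montage size;
- optionally, the same pattern during the 400 ms before frame 2
  (*preactivation*), at `preactivation_effect` (default 0.5) and graded by
  the distance of the trial's frequency from the subject median — no
  prediction without evidence at the boundary, full strength at the
  extremes. In `efficient_only` mode only percept-consistent trials get it.

Subject peak frequencies are drawn 1 Hz inside the band edges (so percept
offsets and jitter stay in band); thresholds follow
`slope·(1000/peak) + intercept + N(0, sd)` with default (1, 10 ms, 5 ms).
The pretest observer and the main-experiment behavior (explicit accuracy
95%, 1% omissions, slightly slower explicit-EM RTs) are simulated per
subject. All randomness derives from `(seed, subject_index)` seed
sequences, so outputs are bit-identical under a fixed seed.

What the generator does **not** emulate: volume-conducted (spatially
correlated) noise, eye/muscle artifacts, non-stationary alpha amplitude,
realistic forward head models, or continuous recordings. Decoding is
therefore easier per unit pattern amplitude than on recorded EEG (channels
pool i.i.d. noise), and passing recovery tests demonstrates correctness of
the estimators, not field-realistic effect sizes.

## Trial sorting and decoding

Per-trial PAF is the mean instantaneous frequency over a scoring window —
by default the window of the group-level significant GM–EM frequency
cluster (mirroring the data-driven choice in the source protocol), with a
fixed −570…−350 ms (pre-frame-2) override; the data-driven variant reuses
the trials later decoded, a circularity the fixed mode avoids. The median
split takes the PAF of the rank-⌊n/2⌋ trial (1-indexed, ascending) as the
boundary; strictly greater is "high", the boundary trial and its ties are
"low". Cells are matched to the minimum count by seeded subsampling.

The decoder is regularized LDA with shrinkage target `tr(Σ)/p·I` and
λ = 0.1 (the regularization scale is a convention; the value is exposed in
configuration). Features are channel means over 50-ms windows
(`round(width·fs/1000)` samples, clipped at epoch edges; ±25 ms smearing
around stimulus onset is inherent). Training centers default to a 10-ms
grid over −400…+400 ms around frame 2. Scoring is leave-one-out: decision
values of held-out trials are pooled and one Mann–Whitney AUC computed per
(train, test) cell — per-fold AUC is undefined for single-trial folds; a
block-averaged variant is available. Pooled LOOCV decision values carry a
small pessimistic (below-chance) bias under weak signal, which is why the
condition-vs-chance cluster tests are one-tailed (above chance).

## Cluster-based permutation inference

Element-wise paired t statistics are thresholded at the two-tailed
cluster-forming α = 0.05 (positive and negative clusters formed
separately); neighbors (1D runs; 4-connectivity in 2D) form clusters whose
statistic is the element count. The null is the exact paired-design null:
per-subject random sign flips of the differences (vectorized — sums of
squares are flip-invariant), 1000 permutations for time courses and 500
for generalization matrices, recording the maximum cluster size per
permutation. A cluster is significant only if its size **strictly
exceeds** the empirical 95th-percentile order statistic (at
`ceil(0.95·n)`) of the null; Monte-Carlo p = (1 + #{null ≥ size})/(1 + n).

Two calibration properties worth knowing:

- On temporally **white** null noise, suprathreshold elements are isolated
  and max cluster sizes rarely exceed 2, so the measured family-wise error
  rate is far below the nominal 0.05 (conservative, never anticonservative).
  Smooth signals — the realistic case — produce larger clusters and more
  informative nulls.
- When an effect spans the **entire** tested window (as the constant-
  frequency generator produces), the observed max size saturates at the
  window width and the test degenerates toward a sign test across subjects;
  with fewer than about 10 subjects, full-window effects cannot reach
  significance at α = 0.05 regardless of effect size.

Zero-variance elements (e.g. AUC exactly 1.0 in every subject under a
saturated decoder) have undefined t and are masked out of cluster
formation with a warning — a conservative choice that only bites far above
any decision boundary.

## Group-level analyses

The between-subject analysis reports Pearson r (two-tailed) between peak
alpha frequency and threshold, and regresses threshold on cycle length
`1000/f`, testing the slope against 1 with `t = (slope − 1)/SE` on n − 2
degrees of freedom. Calibration is verified by simulation (null r exceeds
its 5% critical value ≈ 5% of the time; a generating slope of 1 is
rejected ≤ 10% of the time under the default coupling noise).

## Problem sizes

The test suite exercises cohorts of 5–17 subjects with 40–160 bistable
trials, 16–64 channels; the full recovery run uses the complete study
conditions (17 subjects, 160 trials, 64 channels, 1000/500 permutations)
and completes in well under a minute per cohort. Calibration simulations
use 200 null datasets of 17 × 129 elements.

## Known limitations

- The epoch container is a package-specific flat-file format; an EDF import
  shim is stubbed in the CLI design but not implemented.
- The adaptive-staircase threshold procedure used for intracranial patients
  is out of scope; the intracranial path is covered by the 500 Hz sampling
  variant and all-channel (top-k contact) selection only.
- Wavelet/multitaper spectral estimation, cluster-mass/TFCE statistics and
  nonlinear classifiers are deliberately not provided.
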