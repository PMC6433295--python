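# pafpipe

Analysis pipeline linking **prestimulus alpha frequency (PAF)** to bistable
apparent-motion perception, for electrophysiologists studying how intrinsic
oscillatory dynamics bias perceptual inference.

In a two-frame Ternus-type display, perception alternates between *element
motion* (EM — the frames are integrated over time) and *group motion* (GM —
the frames are segregated). If the alpha cycle gates the temporal window of
integration, then (i) across subjects the transition interframe interval (IFI)
threshold should track the alpha cycle length `1000/f` ms, and (ii) within a
subject, trials with faster prestimulus alpha should end in GM percepts.
`pafpipe` implements the full analysis chain needed to test this on epoched
recordings, and ships a synthetic-cohort generator with known ground truth so
every stage is verifiable end to end without any recorded data.

The stages:

1. **Psychometrics** — behavioral cleaning (omissions, ±3 SD reaction-time
   outliers, incongruent explicit reports) and a binomial maximum-likelihood
   logistic fit `P(GM | IFI) = 1 / (1 + exp(−(IFI − a)/b))`; the transition
   threshold is the 50% point `a`.
2. **Spectral** — FFT amplitude spectra (5–30 Hz), peak-alpha and
   strongest-alpha-channel selection over a posterior region of interest,
   mirror padding, a zero-phase plateau band-pass (flat over 8–13 Hz, 15%
   transition zones), and instantaneous frequency as the unwrapped
   phase derivative of the analytic signal scaled by `fs/2π`, robustified by
   a 10-window median-filter cascade (10–400 ms windows, pointwise median).
3. **Trial sorting** — per-trial PAF (mean instantaneous frequency over a
   scoring window), a median split into high/low PAF, the
   *efficient* (high∧GM, low∧EM) vs *inefficient* (high∧EM, low∧GM)
   inference conditions, and seeded trial-count matching.
4. **Decoding** — regularized linear discriminant analysis
   `w ∝ (Σ + λ·tr(Σ)/p·I)⁻¹(μ₁−μ₀)` on 50-ms windowed channel amplitudes,
   evaluated as temporal-generalization matrices (train × test time) of
   Mann–Whitney AUC under leave-one-out cross-validation.
5. **Stats** — cluster-based permutation tests (paired t maps, suprathreshold
   clusters, max-cluster-size sign-flip null, strict 95th-percentile rule)
   for 1D time courses and 2D generalization matrices, plus the
   between-subject Pearson correlation and the cycle-length slope-vs-1 test.

## Worked example

Fit a psychometric curve to a simulated 2AFC observer (threshold 140 ms,
slope 0.06/ms, 40 trials per IFI):

```python
from pafpipe import generate_psychometric_responses, fit_logistic

table = generate_psychometric_responses(threshold_ms=140, slope_per_ms=0.06,
                                        n_per_ifi=40, seed=3)
fit = fit_logistic(table)
print(fit.summary())
```

```
Logistic psychometric fit (binomial ML)
==========================================
threshold (50% point)      140.00 ms
slope                      0.0628 /ms
R^2 (per-IFI props)        0.9975
identifiable                 True

  IFI(ms)   n    P(GM) obs   P(GM) fit
       50   40       0.025       0.003
       80   40       0.025       0.023
      110   40       0.100       0.132
      140   40       0.475       0.500
      170   40       0.900       0.868
      200   40       0.975       0.977
      230   40       1.000       0.997
```

The estimated threshold lands on the generating 140 ms and by construction
the fitted curve crosses 0.5 exactly there. Recover a within-subject
frequency–percept coupling from synthetic epochs:

```python
from pafpipe import (SimConfig, generate_subject_epochs, mirror_pad,
                     bandpass_plateau, instantaneous_frequency,
                     condition_contrast_series)

cfg = SimConfig(n_trials_per_condition=40, n_channels=16, snr=2.0,
                freq_offset_gm=0.3, seed=5)
ep = generate_subject_epochs(cfg, 0)
pre = ep.crop(-800, 0).pick_channels(["Oz"])
series = instantaneous_frequency(bandpass_plateau(mirror_pad(pre)))
con = condition_contrast_series(series, ep.trials["percept"])
sel = (con.times >= -600) & (con.times <= -200)
print(f"GM-EM frequency difference {con.difference[sel].mean():.3f} Hz")
```

```
GM-EM frequency difference 0.313 Hz
```

— the estimator recovers the generating 0.3 Hz GM offset from trials at
SNR 1:2 alpha-to-noise. The full chain (simulate → psychometrics → alpha →
sorting → decoding → cluster statistics) runs from the command line:

```sh
pafpipe run-all --seed 1 --out results/
```

which writes `results/report.json` with every statistic, seed, trial count
and the configuration hash.

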