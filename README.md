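# medisig

Signal-processing and statistics toolkit for a two-condition
(meditation vs. control) protocol recording 32-channel scalp EEG and a
respiration belt. It is written for physiological-signal researchers who
want an objective, classifier-based marker of the meditative state and a
fully reproducible path from raw sessions to statistics.

Four analyses share one pipeline:

1. **Spectral** — Bartlett-averaged periodograms with a 4-term
   Blackman–Harris taper,
   `P(w) = (1/K) Σ_k (1/N) |Σ_n x_k[n] w[n] e^{-jwn}|²`,
   aggregated into band × scalp-region powers (theta [4,8), alpha
   [8,12), beta [12,30) Hz; six regions) and tested with a two-way
   within-subject ANOVA (Condition × Location), Box-Cox transformed when
   non-normal.
2. **Respiration time-frequency** — the Stockwell transform
   `S(f,n] = Σ_m x[m] (|f|/√(2π)) e^{-(n-m)²f²/2} e^{-i2πfm}`,
   whose frequency-dependent Gaussian window gives wavelet-like
   resolution with absolutely referenced phase; condition contrast by a
   one-factor within-subject ANOVA on coefficient amplitudes.
3. **Phase synchrony** — the phase-lock value
   `PLV(f,n] = (1/L)|Σ_m e^{jθ(f,m]} v[n-m]|` of S-transform phase
   differences over 2-s rectangular windows, thresholded at the 0.9
   quantile of PLVs pooled from 500 phase-randomized surrogate pairs,
   and counted over cross-region electrode pairs per band and condition.
4. **Classification** — per-sample S-transform amplitude feature vectors
   thinned at the first local minimum of the kernel-CCA dependency index
   `I_KCCA(l)` between the sequence and its lag-l shift, min-max
   normalized, and classified with an RBF-SVM under block-wise
   cross-validation; EEG-only, respiration-only and joint
   (concatenated) classifiers are compared.

A synthetic-session generator produces condition-labelled EEG +
respiration with the structure these analyses target (band-specific
power shifts, cross-region phase coupling, slower and deeper meditation
breathing, injectable blink/voltage/flat artifacts), so the whole
pipeline is testable without access to recordings. Sessions round-trip
through EDF. See `docs/methods.md` for models, defaults and limitations.

## Worked example

Generate a 4-subject synthetic cohort and run the spectral, respiration
and synchrony stages (the classifier needs multiple blocks per
condition; see below):

```python
from medisig import PipelineConfig, SyntheticConfig, run_pipeline

config = PipelineConfig(
    synthetic=SyntheticConfig(duration=60.0, seed=5),
    n_subjects=4,
    run_classify=False,
    n_surrogate_pairs=100,        # full-scale default is 500
    phase_grid=(4.0, 32.0, 2.0),
    seed=7,
    out_dir="demo_out",
)
bundle = run_pipeline(config)

theta = bundle["spectral_anova"]["theta"][0]
print("theta condition effect: F(%d,%d) = %.2f, p = %.3g"
      % (*theta.df, theta.F, theta.p))
resp = bundle["respiration_anova"]
print("respiration condition effect: F(%d,%d) = %.2f, p = %.3g"
      % (*resp.df, resp.F, resp.p))
print("PLV threshold (0.9 surrogate quantile):",
      bundle["synchrony_threshold"].threshold)
print(bundle["synchrony_summary"])
```

prints

```
theta condition effect: F(1,3) = 273.46, p = 0.000481
respiration condition effect: F(1,3) = 15.77, p = 0.0285
PLV threshold (0.9 surrogate quantile): 0.597
    condition   band   count
0     control  alpha    1.50
1     control   beta    0.00
2     control  theta    0.00
3  meditation  alpha  406.25
4  meditation   beta    0.00
5  meditation  theta    0.00
```

Read: meditation raises theta band power (F on (1, n−1) degrees of
freedom across the 4 subjects), shifts respiration amplitude (slower,
deeper breathing), and — because the generator couples alpha-band
activity across regions more strongly during meditation — an average of
~406 of the 421 admissible cross-region electrode pairs exceed the
surrogate asynchrony threshold in the alpha band during meditation
versus ~2 during control. `demo_out/` holds the same results as
CSV/JSON, stamped with the configuration hash and seed.

Classification runs per subject over repeated recording blocks per
condition and reports mean cross-validated accuracy for the EEG-only,
respiration-only and joint classifiers. With `classify_demo.json`
holding a desk-scale setup:

```json
{
  "n_subjects": 2,
  "sessions_per_condition": 4,
  "run_spectral": false, "run_respiration": false, "run_synchrony": false,
  "feature_grid": [4.0, 32.0, 2.0],
  "resp_grid": [0.0625, 4.0, 0.0625],
  "classify_channels": ["Fp1", "F3", "Cz", "Pz", "Oz", "T7"],
  "folds": 4,
  "sigma_factors": [0.5, 1.0, 2.0], "c_grid": [1.0, 4.0, 16.0],
  "kcca_max_lag": 8, "kcca_max_n": 250, "max_feature_samples": 600,
  "synthetic": {"duration": 30.0, "seed": 5}
}
```

```bash
medisig simulate --subjects 2 --duration 60 --out sessions/
medisig classify --config classify_demo.json --out results/ --seed 7
```

prints

```
{
  "eeg": 0.7195945945945946,
  "respiration": 0.8547297297297297,
  "joint": 0.9788851351351351
}
```

— the joint classifier is the most accurate, as expected when EEG and
respiration carry independent condition information; on a cohort
without condition differences all three sit at chance (≈0.5).

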