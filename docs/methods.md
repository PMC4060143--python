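# Methods

`medisig` analyses labelled EEG + respiration sessions recorded under two
conditions (meditation vs. control) with four coupled analyses —
band-power spectral statistics, respiration time-frequency contrast,
phase-synchrony counting, and supervised classification — and ships a
synthetic-session generator that realizes the condition structure those
analyses target. This note records the models, the defaults and why they
were chosen, and the known limits of what the synthetic experiments can
show.

## Signal model of the synthetic generator

Each EEG channel is a sum of spectrally shaped Gaussian-noise rhythms
plus a background:

* theta — Gaussian spectral peak at 6.0 Hz (sigma 0.7 Hz);
* alpha — narrow eyes-closed peak at 9.5 Hz (sigma 0.4 Hz);
* beta — broad 12–30 Hz band with 0.5 Hz raised edges;
* background — power ∝ 1/f² between 0.5 and 40 Hz.

Rhythm standard deviations are region-dependent (occipital alpha
dominance, frontal theta, weak beta; 2.5–8 µV) and the per-condition
`band_power` multipliers scale each rhythm's **variance**, so a
multiplier of 2 doubles that band's PSD. Meditation defaults raise theta
and beta power in (nearly) all regions and alpha mainly over occipital
and right-temporal sites; the frontal theta multiplier is 1.00, i.e. the
generator deliberately encodes a null cell there. Two realism terms add
variability: a per-subject trait gain per band (log-sd 0.15, shared by
both conditions of a subject) and a per-session gain wobble (log-sd
0.05) that models session-to-session nonstationarity.

Cross-region phase coupling mixes one session-wide shared alpha-band
component into every channel with coefficient `c`
(`sqrt(1-c^2)·own + c·shared`, keeping band variance calibrated).
Defaults: meditation 0.9, control 0.3. These values were chosen from the
phase-lock-value arithmetic: the PLV between two coupled channels is of
the order of the shared-power fraction `c²`, so counting any pair as
synchronous against a threshold in the 0.6–0.8 range requires `c²` well
above it — coupling near 0.9 in the synchronous condition and well below
the threshold (0.3) in the other.

Respiration is a quasi-sinusoid at the condition's breathing rate
(meditation 0.13 Hz, control 0.25 Hz — configurable; chosen to be
realistic and to respect the direction of the slowing effect), with slow
amplitude and frequency modulation (<0.02 Hz), a per-session rate offset
(sd 0.03 Hz), and depth scaling `(0.25/rate)^0.5`: slower breathing is
deeper (tidal-volume compensation). The depth term matters statistically:
a pure frequency shift redistributes spectral mass without changing the
frequency-averaged amplitude, so an overall condition main effect on
respiration amplitude exists only because slower breaths are larger.

Artifacts are injectable, not default: 0.5-s raised-cosine blinks with a
frontal-dominant spatial profile (only their removability matters),
rectangular high-voltage excursions, and channels rescaled below the
flat-channel bound.

What the generator does **not** emulate: volume conduction and realistic
channel covariance, non-stationary rhythm frequency drift, EMG/ECG
contamination, or any relation between EEG and respiration beyond the
shared condition label. Passing tests therefore demonstrate that the
pipeline recovers effects of the modelled kinds at realistic
signal-to-noise, not that real recordings would classify at the same
accuracy.

## Preprocessing

Linear-phase FIR filters are designed from band edges with equiripple
(Parks–McClellan) design, falling back to a Kaiser windowed-sinc when
the estimated order exceeds ~1200 taps (very sharp edges such as a
0.1 Hz high-pass). The promised tolerances are ±0.5 dB passband and
40 dB stopband; the realized designs target 0.1 dB/45 dB so the
promises hold with margin and double filtering perturbs passband content
by well under 1%. Filtering compensates the group delay exactly; one
filter length at each end is a transient and `discard_transient`
(default: one filter length, applied at the head) removes it.

Amplitude artifact handling: samples beyond ±200 µV are rejected with a
0.1 s guard margin; a channel whose running 1-s peak stays below 2 µV is
flat there, and a channel flat for more than half the session is dropped.
Rejected spans never enter segment formation for PSD estimation. Ocular
cleanup estimates a logistic-infomax ICA unmixing and zeroes components
whose absolute Pearson correlation with an ocular reference (an EOG-like
series, or the low-passed Fp/AF mean) exceeds 0.7. Decimation to 64 Hz
is plain integer-stride subsampling guarded by a spectral check that at
most 5% of power lies above the target Nyquist.

On sessions shorter than four periods of the lowest cut-off, the 0.1 Hz
(EEG) and 0.01 Hz (respiration) high-passes cannot be resolved and mean
removal stands in; the two are indistinguishable at that scale.

## Spectral analysis

The Bartlett estimator averages periodograms of consecutive
non-overlapping segments tapered with a 4-term Blackman–Harris window
(−92 dB sidelobes), with only the 1/N normalization — absolute units are
arbitrary but condition ratios are preserved. Default segment length is
256 samples (4 s at 64 Hz, 0.25 Hz resolution), matching the classifier's
frequency grid. Band powers average over theta [4,8), alpha [8,12), beta
[12,30) Hz and over each of six scalp regions (frontal, central,
parietal, occipital, right/left temporal).

The Condition × Location analysis is a classical two-way within-subject
ANOVA computed from sums of squares, each effect tested against its own
subject-interaction stratum: condition on (1, n−1), location on
(5, 5(n−1)), interaction on (5, 5(n−1)) degrees of freedom for six
locations. Two aggregation units are provided: the default collapses to
one value per subject × condition × region; the per-frequency option
treats band frequencies as within-subject replicates (blocking unit =
subject × frequency), which inflates error degrees of freedom and F
values accordingly. Values are Box-Cox transformed (profile-ML lambda)
only when a Shapiro–Wilk test rejects normality at α = 0.05. Sums of
squares below 10⁻¹² of the table's total variation are treated as exact
zeros so that a constant table yields F = 0 rather than a ratio of
rounding noise.

## Stockwell transform

The S-transform uses a Gaussian window whose standard deviation is one
period (1/f); frequencies are accepted in Hz and converted to
cycles/sample internally, which fixes the window expression's time
unit at sample index. The implementation demodulates at each grid
frequency and convolves with the Gaussian via zero-padded FFTs — a
linear, not circular, convolution, padded ten window-sigmas beyond the
signal — and matches the direct O(N²) double summation to < 1e-8. Grids:
respiration [0.0625, 16] Hz at 0.0625 Hz; EEG phase analysis 4–32 Hz at
1 Hz; EEG features [4, 32] Hz at 0.25 Hz. The respiration condition
contrast averages coefficient amplitudes per subject and condition
(Box-Cox as above) and runs the one-factor within-subject ANOVA on
(1, n−1) degrees of freedom; the per-frequency replicate unit exists as
an option but interacts badly with Box-Cox when most of the grid holds
near-zero amplitudes (a negative lambda lets the off-band noise dominate
the transformed variance), so the subject-level unit is the default.

## Phase synchrony

PLV is the modulus of the rectangular-windowed mean of
`exp(j·theta)` where theta is the wrapped S-transform phase difference
of an electrode pair; windows are 2 s, sliding one sample (evaluated by
cumulative sums, equal to naive per-window recomputation to < 1e-12).
The asynchrony threshold pools windowed PLVs from 500 pairs of
phase-randomized surrogates — inverse FFTs of the reference's amplitude
spectrum with i.i.d. uniform phases, preserving the periodogram exactly —
over all grid frequencies and takes the empirical 0.9 quantile of the
pooled histogram (2000 bins).

The threshold is a property of the *reference spectrum*, not only of the
procedure: a surrogate's Stockwell phase at frequency f decorrelates at
the inverse of the local spectral width around f, so narrow spectral
peaks (eyes-closed alpha) produce slowly wandering phases, high windowed
PLVs and a high pooled quantile, while spectrally flat references
produce Rayleigh-like small values (≈ sqrt(π/4L_eff)). With the
generator's physiological reference the pooled 0.9 quantile lands near
0.55–0.60; per-frequency quantiles range from ≈0.73 at 4 Hz to ≈0.27 at
32 Hz. Values much higher than that would require near-locked surrogate
phases across a large fraction of the grid, which no realistic spectrum
produces. Because of this sensitivity the pipeline records the full
pooled histogram and provenance with every threshold, offers a
per-frequency alternative, and accepts a fixed override.

Counting: only cross-region electrode pairs are admissible; a pair
counts once per band when the median over window positions of its
band-averaged PLV exceeds the threshold; the per-pair summary also keeps
the mean. The pair set is fully configurable since region partitions
vary between montages.

## Features and classification

Feature vectors are per-time-sample concatenations of S-transform
amplitudes over channels. Consecutive vectors are redundant, so the lag
`L` at which the kernel canonical correlation `I_KCCA(l)` between the
sequence and its lag-l shift reaches its first local minimum
(`I(L−1) > I(L) ≤ I(L+1)`) becomes the thinning factor; the retained set
is every L-th vector, floor(N/L) in total.

The KCCA estimator: Gaussian kernels with median-pairwise-distance
width, double-centred Gram matrices on at most 500 anchor points, and
the first canonical correlation of the generalized eigenproblem with a
coefficient-ridge `kappa` (default 0.02) on each side:
`rho² = lambda_max((Kx²/n + kI)^-1 KxKy/n (Ky²/n + kI)^-1 KyKx/n)`,
evaluated by two Cholesky solves and power iteration. One anchor set and
one kernel width are shared across all lags so the lag curve's shape
reflects dependency rather than resampling noise, and the local-minimum
upturn comparison carries a slack of `0.4/sqrt(n_anchors)` — the scale
of the index's finite-sample jitter — so flat-curve noise neither
fabricates nor masks a minimum. With no qualifying lag the factor falls
back to `max_lag` with a warning.

Features are min-max normalized to [0, 1]. Two modes exist: bounds
computed per split group (train/validation/test each on its own
extremes) and the default leakage-safe mode that computes bounds on the
training group and applies them everywhere. The per-group mode erases
level information from any single-condition test block and is kept only
for protocol fidelity.

The classifier is an RBF-kernel SVM. Cross-validation folds are
contiguous recording blocks, interleaved by class so every fold holds
(near-)equally many blocks of each condition — with one block per fold a
degenerate majority-class predictor is wrong on every held-out block,
biasing accuracy far below chance, so paired-block folds are essential
for an honest chance level. Hyperparameters (sigma ∈ {2⁻⁴…2⁴} × median
distance, c ∈ {2⁻²…2⁶}) are selected per fold on a validation group
carved out of the training folds, refit on train+validation, and scored
once on the held-out fold; the reported accuracy is the mean of those
held-out scores and is unbiased under the null (verified: a cohort with
no condition effect scores 0.45–0.55). A `cv-max` mode that reports the
grid maximum of the pooled cross-validated accuracy is available; it is
optimistic by the selection noise.

Per subject, EEG-only, respiration-only and joint (concatenated, then
re-thinned by KCCA) classifiers are trained; the cohort summary averages
accuracy across subjects. Decision-function values of the held-out
samples are exported as a candidate graded "meditation depth" score.

## Pipeline and reproducibility

`run_pipeline` derives every stage's seed from the master seed with
CRC-stable hashing, so toggling one stage never shifts another's
randomness, and stamps every output with the configuration hash. Stage
failures are reported per stage; downstream stages that need a missing
input (e.g. classification without a respiration channel) fail fast with
a named error. Sessions round-trip through a minimal 16-bit EDF writer
(physical range per channel, so quantization error is range/65536) and
are read back with `mne`.

## Problem sizes in the shipped experiments

The test-suite experiments run at desk scale chosen as the smallest
cohorts at which the targeted effects are comfortably resolved:
10 subjects × 90 s sessions for the band/region direction pattern,
10 subjects × 60 s for the respiration contrast, 20 single-subject
seeds × 30 s for the synchrony contrast (12 electrodes over six
regions), and 20 subjects × 8 blocks of 30 s for the classifier
ordering with 6 electrodes, a 2 Hz feature grid and at most 600 retained
vectors per subject. The surrogate threshold is always computed at its
full operating point (15 min, 500 pairs). Defaults in the public API
remain at the full-scale values.

## Known limitations

* The surrogate PLV threshold depends strongly on unstated properties of
  the reference spectrum (see above); thresholds from different
  references are not comparable, and the stored histogram should
  accompany any reported value.
* The per-frequency ANOVA units inflate degrees of freedom by treating
  correlated frequencies as replicates; they are provided for
  comparability, not recommended for inference.
* Logistic (non-extended) infomax separates super-Gaussian sources only;
  it removes blinks but would not isolate sub-Gaussian artifacts such as
  line noise.
* The EDF writer emits 16-bit EDF with per-channel physical scaling and
  1-s records; it does not write annotations, patient metadata or BDF.
* KCCA-based thinning is an O(n³) estimator on the anchor set; its lag
  curve is noisy below ~150 anchors and the selected factor can then sit
  one lag away from the asymptotic one.
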