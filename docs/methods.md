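# Methods

This note documents the models, numerical choices and limitations behind
`pwvlab`. It covers what the synthetic phantom does and does not emulate,
how each estimator is specified, and which knobs matter.

## Physical model

The package targets a thin-walled elastic tube filled with an incompressible
fluid, for which the Moens–Korteweg relation links wave speed to wall
stiffness:

    PWV = sqrt(E * W / (rho * d))

with Young's modulus `E` (Pa), wall thickness `W` (m), fluid density `rho`
(kg/m³) and inner diameter `d` (m). Defaults are `rho = 1000 kg/m³`,
`d = 10 mm`, sensor separation `D = 0.30 m`; all three are overridable
through `PwvConstants`. These constants are the ones under which the
package's golden elasticity/velocity tables are self-consistent.

Wall material is characterized by Shore A hardness, mapped to `E` (MPa) by
five empirical conversions for silicone elastomers:

| model  | E(S), MPa                                             |
|--------|-------------------------------------------------------|
| DMA    | 0.2354·e^(0.0657 S)                                   |
| Gent   | 0.0981·(56 + 7.62336 S) / (0.137505·(254 − 2.54 S))   |
| RDA    | 0.1611·e^(0.058 S)                                    |
| Ruess  | e^(0.0235 S − 0.6403)                                 |
| Secant | 0.1614·e^(0.0541 S)                                   |

All five are strictly increasing on the validated range S ∈ [10, 50]; Gent
is singular at S = 100. Unrounded elasticity always feeds the
Moens–Korteweg step — rounding E to two decimals first perturbs velocities
at the second decimal. Ruess is the default conversion (it tracks measured
velocities most closely in this class of phantom); every API accepts the
model name.

## Synthetic phantom

`pwvlab.synthgen` generates multi-channel records with exact ground truth.
One cardiac cycle is a closed-form two-lobe pulse on a constant baseline:

    s(t) = offset + A_s·G(t; mu_s, s_s) + A_d·G'(t; mu_d, s_dl, s_dr)

`G` is Gaussian; `G'` is an asymmetric Gaussian, narrow on the left flank
(so a distinct dicrotic notch can exist) and broad on the right
(`s_dr = 0.22 T`), so pressure decays through diastole into a sharp,
well-defined foot the way real pressure pulses do. A purely symmetric
two-Gaussian shape was rejected: its flat inter-beat gap makes the foot
position ill-conditioned, and foot jitter under noise then swamps transit
times of a few tens of milliseconds.

Morphology follows affine maps of the setup condition, calibrated once to
keep features in plausible ranges:

* pulse pressure `PP = 8 + 0.4·SV + 0.25·ShA` (mmHg) — 14–29 mmHg over the
  grid, increasing with hardness;
* target systole fraction `0.28 + 0.002·ShA`; the realized fraction
  (measured on the template, stored in the truth bundle) spans 0.39–0.54 and
  is monotone in hardness;
* dicrotic amplitude `(0.25 − 0.004·ShA)·A_s` — the notch fades with
  stiffness and degenerates into a shoulder for ShA ≳ 30, so notch
  detectability is intentionally partial, as on a physical phantom.

The downstream channels are the upstream waveform evaluated at
`t − position/PWV` (exact closed-form evaluation, i.e. genuinely fractional
sample delays) and attenuated by `0.95^(position/D)`; PWV comes from the
configured conversion model, so `delay = D / PWV` is known exactly.
Channel layout: pressure at 0 and 30 cm (`p1`, `p2`), capacitive at 5 and
25 cm (`c1`, `c2`); capacitive channels share the pressure waveform shape,
which is a simplification (volume and pressure pulses differ in morphology
on real hardware).

Nuisance terms: white noise with σ = 2 % of pulse pressure per channel
(independent), plus a drift sinusoid (amplitude 1 signal unit, 0.05 Hz —
below the 0.2 Hz baseline cutoff so conditioning can cancel it), baseline
offset 30 mmHg. Per-record substreams are derived from
`SeedSequence([seed, record_index])`: identical seeds are bit-reproducible,
duplicate grid entries get fresh noise.

What the generator does **not** emulate: fluid–structure interaction, wave
reflections, viscoelastic walls, non-Newtonian fluid, sensor-specific
transfer functions, or any waveform-shape difference between pressure and
capacitive channels. Tests passing on this phantom show the pipeline's
machinery is correct and self-consistent — not that it is accurate on
measured data.

## Conditioning

Filters are 4th-order Butterworth applied forward-backward
(`sosfiltfilt`), hence zero-phase: landmark positions shift < 1 sample
through the chain. High-pass cutoff 0.2 Hz; low-pass cutoff selected from
the nominal pump rate (nearest of 30/60/80 bpm → 3/6/8 Hz), which keeps at
least four harmonics; rates above 120 bpm are rejected rather than guessed.
The fundamental-frequency estimator (Welch, 8 s Hann segments, 50 %
overlap, argmax in [0.2, 3] Hz) is available for diagnostics and flags
low-confidence spectra (peak < 3× median band power). Normalization to
[0, 1] is per trial and returns offset/scale so pulse pressure is always
computed from pre-normalization amplitudes.

## Fiducial detection

Beats are segmented around systolic peaks (prominence 30 % of range,
refractory period 0.6 nominal cycles), windows midpoint-to-midpoint.
Within a beat: foot = last −→+ sign change of the first derivative before
the peak (argmin fallback); rising steep = first-derivative maximum between
foot and peak; falling steep = end of the first-derivative descent after
the peak; dicrotic notch = first +→− third-derivative zero crossing after
the peak, reported only when a dicrotic lobe forms a local maximum with
≥ 1 % prominence after the descent (otherwise a pure-Gaussian tail would
always yield a spurious crossing at ~√3 σ past the peak). Beats violating
foot < rising < peak < falling are dropped, not repaired.

On noise-free records the signal is already band-limited and detection runs
directly on the raw channels; localization is then within ±2 samples of
truth across the whole grid. Under noise the filtered chain is required,
and individual feet can jitter (especially at the 3 Hz cutoff); the
median-across-beats aggregation absorbs this.

## Features and hardness estimators

Per beat: crest time (foot→peak), systole time (foot→falling steep), pulse
pressure (foot-to-peak, pre-normalization), pulse-to-pulse interval
(foot-to-foot). Durations are normalized to % of the median cycle length —
this removes nominal-rate differences so trials are comparable. Aggregation
is the median (robust to occasional mis-detections); fewer than 5 beats is
tolerated but low-confidence.

The OLS estimator regresses ShA on (ST, PP, SV, HR, W) after removing
observations with Cook's distance above 4/n (single pass, full-data fit).
ST enters the pipeline as fraction-of-cycle; the fitting operations
themselves are unit-agnostic.

The ANFIS is first-order Sugeno: 6 inputs (SV, HR, W, crest %, PP,
systole %), 2 Gaussian membership functions per input placed at the
min/max of each standardized column with width = half the column range,
full grid rule base (2⁶ = 64 rules), affine consequents (64 × 7 = 448
parameters, 24 premise parameters). Hybrid training, 30 epochs by default:
each epoch solves all consequents jointly by least squares (ridge 1e−8 for
near-degenerate firing patterns; the training SSE never increases across
this step) and then takes one normalized batch-gradient step on centers and
widths with a Jang-style adaptive rate (×1.1 on improvement, ×0.5 and
revert on worsening; σ floored at 1e−4). Data are split 75/25, stratified
by hardness level, fixed seed. With one rule the model reduces exactly to
OLS, which the tests exploit as a cross-check against statsmodels.

The benchmark evaluates 14 families — logistic regression, RBF-SVC, kNN,
random forest, histogram gradient boosting (leaf size 5: training folds
hold only a few dozen samples); ridge/poly-ridge/poly-lasso (degree-2
expansions)/RBF-SVR/RF/GB regressors followed by snap-to-nearest-class
(midpoints round up, out-of-range clamps); and three small neural baselines
(softmax MLP, CORAL ordinal head, MC-dropout with 100 inference passes) —
as two-hidden-layer (32, 16) ReLU networks trained with Adam and early
stopping on an inner stratified 80/20 split (patience 20), implemented in
NumPy. Features are standardized inside each training fold; metrics are
computed on pooled out-of-fold predictions of a stratified 5-fold split;
macro-averaged F1/sensitivity/specificity use the zero-division→0
convention; MAE/RMSE treat class labels as numeric Shore A values.

## Reference PWV and error statistics

The reference transit time pairs per-beat feet between the two pressure
channels (nearest-time matching within half a cycle) and takes the median
difference; a non-positive median raises an orientation error. Reference
records use 2000 samples/s and 30 s duration — at a few dozen beats the
median is stable against the foot jitter that 12 s records could not
absorb. PWV errors against truth are median ~2 % with a heavy tail at the
fastest configurations (transit ~16 ms), where each millisecond of foot
error is ~6 % of the delay.

`error_analysis` computes paired differences and gates the location test on
Shapiro–Wilk at α = 0.05: normality not rejected → two-sided one-sample
t-test; rejected → two-sided Wilcoxon signed-rank (zeros dropped, normal
approximation above n = 25). All-zero differences short-circuit to a
degenerate flag.

## Problem sizes and determinism

Default study sizes: 90 setups, 30 s records at 200 samples/s for features
(15–40 beats per trial), 30 s at 2000 samples/s for the reference; the full
pipeline runs in ~10 s on one core. Every stochastic stage takes an
explicit seed (generator substreams, ANFIS split, CV folds, network
initialization); identical configurations reproduce bit-identical reports.

## Known limitations

* The generator's morphology maps are plausibility-calibrated, not fitted
  to measured phantom data; absolute regression coefficients on synthetic
  features are not comparable to coefficients fitted on real measurements.
* Capacitive channels are delayed/attenuated copies of the pressure pulse.
* The ANFIS interpolates its 448 consequents from ~67 training rows; on
  data with weaker feature–hardness structure than the phantom it will
  overfit — the holdout curve in `TrainHistory` is the guard.
* The dicrotic notch is only detectable at low hardness by design; notch
  detection rates below 100 % are expected and notch-derived features are
  never used downstream.
* Cook's threshold 4/n is a convention; the number of removed observations
  is data-dependent.
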