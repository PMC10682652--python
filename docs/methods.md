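# Methods

## The measurement problem

In severe aortic stenosis (AS), especially in the low-gradient phenotype,
the usual pressure-derived severity indices (mean gradient, valve area,
valvuloarterial impedance) correlate poorly with how much a patient
actually stands to gain from valve replacement. The approach implemented
here quantifies stenotic burden from the *interaction* of flow and
pressure over the ejection phase: the parametric curve of LVOT flow
velocity (pulsed Doppler, cm/s, abscissa) against ascending-aorta pressure
(invasive, mmHg, ordinate) over one averaged cardiac cycle — the
velocity-pressure (VP) loop.

From the loop we read the landmarks

* `Vmax`, `t_Vmax` — peak LVOT velocity and its time after the R-peak;
* `Vo` — velocity at ejection onset (first mesh point reaching 5% of
  `Vmax`; configurable threshold);
* `P(Vo)` — taken as the beat's minimum (diastolic) pressure;
* `P(Vmax)` — pressure at `t_Vmax`;
* `Pmax`, `t_Pmax` — peak systolic pressure and its time,

and the index

```
slope_index = [P(Vmax) − P(Vo)] / Vmax        (mmHg per cm/s)
```

With velocity and pressure plotted in native units (1 cm/s and 1 mmHg one
axis unit each) and angles measured from the velocity axis,
`tan(ALPHA) = slope_index` holds as an algebraic identity, so the ALPHA
angle and the ratio are interchangeable parameterizations. A
well-coupled ventricle-aorta system catches a large pressure rise by the
time velocity peaks (large index); a heavily loaded valve decouples the
two and the index collapses toward zero. A simplified clinical path
avoids loop construction entirely: both recordings carry the same ECG
lead, so `P(Vmax)` can be estimated by applying the R-wave-to-Doppler-peak
delay to the pressure curve, and `P(Vo)` is the diastolic pressure. The
package implements both paths and tests their agreement.

### BETA and GALA chords

The BETA and GALA angles are reported alongside ALPHA in the VP-loop
literature but their published definitions use quantities this package
does not extract. They are implemented here as provisional chord angles
using only the named landmarks — BETA from `(Vmax, P(Vmax))` to
`(V(Pmax), Pmax)`, GALA from `(0, P(Vo))` to `(V(Pmax), Pmax)` — each
isolated in one function (`beta_angle_deg`, `gala_angle_deg`) so the
definitions can be swapped without touching anything else. They reproduce
the expected orderings (BETA ≫ ALPHA) but should not be compared
quantitatively against other implementations.

## Signal processing

* **Beat segmentation** is R-peak gated; each beat covers one R-R
  interval with time re-expressed from its R-peak. If no sample falls on
  the R-peak the value there is linearly interpolated so beats start at
  relative time 0. The final partial beat is discarded.
* **R-peak detection** (used only when no annotation file is supplied)
  thresholds the rectified ECG at mean + 2.5 SD over a sliding 2-s
  window with a 0.2-s refractory period. This is adequate for clean
  laboratory or synthetic signals and is not a QRS delineator; a manual
  annotation file always overrides.
* **Meshing** resamples each beat by piecewise-linear interpolation onto
  a uniform mesh of N = 256 points (default) spanning the beat. Linear
  interpolation is the least-assumption choice for digitized curves and
  is exactly testable; 256 points resolve 1-2 ms features at typical
  heart rates. Endpoints are preserved exactly.
* **Averaging** is the pointwise mean over beats, customarily 20 (a
  warning — never an error — flags fewer). Beats of unequal duration are
  time-normalized to the median R-R duration before averaging: only the
  mesh is rescaled, sample values are untouched. This choice prevents
  diastolic smearing when heart rate drifts; it assumes morphology scales
  with cycle length, which is adequate over the ±10% duration mismatch
  the loop builder accepts.
* **Ties** in velocity or pressure maxima take the first occurrence, for
  determinism.

Units are seconds, mmHg, cm/s throughout; within a beat the R-peak is
t = 0.

## Endpoint rules

Objective functional improvement at 6 months is disjunctive and
inclusive: ≥ 10% gain in 6-minute-walk distance, or — only when that gain
is absent — ≥ 50% drop in NT-proBNP relative to baseline. Death handling:
death before day 30 from heart failure counts as no improvement, from any
other cause as exclusion (no functional data exists); death between day
30 and 6 months falls back to the 30-day evaluation under the same two
criteria, negated if heart failure occurred or caused death afterwards.
Subjective improvement is ≥ 1 NYHA class gained and/or ≥ 10 KCCQ points.
Percentages are reported over the non-excluded denominator to one
decimal. NT-proBNP is compared as a ratio, never as an absolute
difference, and excluded patients never enter model fitting or
denominators.

## Cohort statistics

* **Screening**: Shapiro-Wilk (p ≥ 0.05 in both groups) selects Welch t
  vs Mann-Whitney for continuous variables; categorical tables use
  chi-square, or Fisher's exact when an expected cell is below 5 (2×2).
  Predictors pass the screen at p < 0.2.
* **Partition**: stratified by outcome, reproducible under an explicit
  seed; train-set class proportions match the cohort to within one
  patient.
* **ROSE balancing**: the smoothed bootstrap — pick a class with
  probability 1/2, a seed observation uniformly within it, and add
  zero-mean Gaussian noise with per-dimension bandwidth
  `h_j = (4/((q+2) n_k))^{1/(q+4)} · sd_j` (q predictors, class size
  `n_k`, within-class SD `sd_j`), multiplied by a shrink factor
  (default 1; 0 degrades to a plain bootstrap). Generated minority
  points therefore have per-dimension SD `sqrt(sd_j² + h_j²)`, which the
  tests check as a closed form.
* **Stepwise logistic regression**: backward elimination dropping the
  largest Wald p until all retained p < 0.05 (AIC-based elimination
  behind a flag). Reported with odds ratios and Wald 95% CIs,
  Hosmer-Lemeshow over 10 risk deciles (df = 8), Nagelkerke R², and an
  events-per-variable warning below 10. Separation raises a named error
  rather than returning unstable estimates.
* **Bagged ensemble**: `n_models` (default 100) logistic refits on
  ROSE-balanced bootstrap resamples; the ensemble predicts the mean
  member probability (majority vote behind a flag). Members that fail
  (e.g. separation in a resample) are skipped with a warning. Exposed as
  the sklearn-compatible `BaggedROSELogistic`.
* **ROC**: empirical curve; trapezoidal AUC (= Mann-Whitney concordance
  probability, verified against exhaustive pair enumeration); DeLong
  variance for the CI; Youden-J cutoff with ties resolved toward the
  lower cutoff. The reference cutoff of 0.1 on the slope index is a
  documented literature value, never a constant in the code.
* **Survival**: Kaplan-Meier product-limit curves per group, log-rank
  comparison, hazard ratio from a single-covariate Cox fit, cumulative
  mortality read from the curves at 730 days.

All stochastic operations take explicit seeds (default 20231114).

## The synthetic generator

### Waveforms

Pressure is an exactly periodic composition of an exponential diastolic
decay (time constant 0.40 s) toward the configured diastolic value, a
raised-cosine upstroke from the beat's minimum pressure to the systolic
value, and a Gaussian dicrotic notch; velocity is a half-cosine rise over
the acceleration time (default 120 ms, the prolonged value typical of
significant AS) and a half-cosine fall to end-ejection. Both are sampled
at 250 Hz (fluid-filled-manometer bandwidth scale) over 25 beats with
recorded R-peaks and optional additive Gaussian noise (the envelope is
clipped at zero). Because every piece is analytic, the generator returns
closed-form landmark values, giving the full pipeline an exact oracle:
with no noise the extracted slope index agrees with the analytic value to
~0.25%.

`severity_decoupling` adds a pure delay to the pressure upstroke relative
to the velocity peak. Since the raised cosine is strictly increasing in
phase, the slope index is strictly decreasing in the delay — the
monotonicity the tests sweep over 0-80 ms. The beat's minimum pressure is
independent of the delay (the decay duration `T − rise_time` is
unchanged), which keeps the sweep a clean one-parameter family.

### Cohorts

Patients carry a ground-truth improvement label (Bernoulli, default
82/102), group-specific baseline covariates, label-consistent follow-up
trajectories, and survival. Covariates are drawn from truncated-at-zero
normals whose parent parameters are solved numerically so that the
*truncated* distribution has exactly the configured group mean and SD
(moment-matched truncation). This matters for the slope index: with the
default group moments (0.09 ± 0.08 vs 0.23 ± 0.19) naive truncation —
using the configured values as parent parameters — inflates the means
asymmetrically and pushes the between-group AUC from the binormal value
Φ(Δμ/√(σ₁²+σ₂²)) ≈ 0.75 up to ≈ 0.82. Moment matching keeps the
empirical AUC within ±0.02 of the closed form at n = 20 000, which the
acceptance suite asserts. A truncated-at-zero normal cannot reach a
coefficient of variation of 1, so such configurations are rejected
explicitly.

Trajectories are generated with safe margins around the endpoint
thresholds (walk-route improvers gain 12-40%, biomarker-route improvers
drop NT-proBNP to 20-48% of baseline with walk gains below 7%, and
non-improvers stay below both bars), so classifying the generated table
recovers the label essentially always — the round-trip property the
tests require at ≥ 99%. Deaths follow per-group exponential hazards with
rates `−ln(1 − mortality₂ᵧ)/730` matched to the configured 2-year
mortality (defaults 9% vs 44%), with independent exponential censoring.
Improvement-group deaths are assigned non-cardiac causes and
no-improvement-group deaths heart-failure causes; this keeps the death
rules label-consistent (early non-cardiac deaths are excluded rather
than flipped) and is a deliberate simplification, not an epidemiological
claim.

### What the generator does not emulate

* Measured physiology: the waveforms are morphological stand-ins, not a
  Windkessel or wave-intensity model; reflections, respiration, arrhythmia
  and catheter artefacts are absent.
* The printed group dispersions are taken at face value as SDs. For
  blood pressure and gradients they are implausibly tight for patient-level
  SDs (they are more plausibly standard errors), which makes those
  covariates *more* discriminative in synthetic cohorts than clinical
  reality — small synthetic cohorts can retain SBP ahead of the slope
  index in stepwise selection. Tests therefore never assert which
  conventional covariate wins, only the behaviour of the machinery.
* Correlations between covariates are not modelled; each is drawn
  independently within its group.

Passing tests therefore demonstrate the correctness of the algorithms and
their implementation under controlled conditions, not clinical
performance on real recordings.

## Numerical choices and degenerate inputs

* Landmark times are mesh times; the quantization error this induces in
  `P(Vmax)` is bounded by the local pressure slope times half the mesh
  step (≈ 0.2 mmHg at defaults) and both estimation paths share it, so
  their mutual agreement is far tighter (< 0.01 mmHg on noiseless
  signals).
* `build_loop` refuses mesh-length mismatches and beat durations
  differing by more than 10%; within that band both channels are placed
  on the mean-duration mesh without value re-interpolation.
* All-zero velocity loops, single-class outcomes, no-event survival
  data, zero pre-values in proportional changes, and SVi/PP ≤ 0 raise
  typed errors rather than propagating NaN.
* Hosmer-Lemeshow groups are deciles of predicted risk via a stable
  argsort; empty groups are skipped.
* DeLong CIs are clipped to [0, 1]; the AUC itself is the exact
  trapezoid/Mann-Whitney value.
* JSON reports are serialized with sorted keys; identical seeds give
  byte-identical files.

## Problem sizes used in the checks

The automated checks run at sizes chosen to make their tolerances
meaningful while staying desk-scale: 20 000 patients for the
closed-form AUC comparison (binomial SE of AUC ≈ 0.004), 40 000 for
moment and mortality-rate checks, 200 replicates for the null
calibrations (log-rank uniformity, Hosmer-Lemeshow 5% rejection), 100
replicates of n = 5000 for coefficient-recovery coverage, and 10 seeds
across 5 severities for the decoupling sweep.
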