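# Methods

## Problem and approach

`capnopred` estimates the two headline spirometric parameters — forced
expiratory volume in one second (FEV1, L) and forced vital capacity
(FVC, L) — from a single-breath volumetric capnogram plus basic
demographics, so that pulmonary function can be screened without a
maximal forced-expiration maneuver. The estimator is a three-part
combination algorithm:

1. **Medical-feature regression** (high-dimensional tabular path). An
   RBF-kernel support-vector machine classifies airflow limitation at
   the GOLD fixed ratio FEV1/FVC < 0.7 (strict inequality) from the
   15-dimensional vector of demographics (male indicator, age, height,
   weight, BMI) and the ten capnogram features. Its raw decision margin
   z is mapped through the logistic function σ(z) = 1/(1+e^−z) — a
   plain sigmoid of the margin, deliberately *not* Platt scaling with a
   fitted slope — and the resulting obstruction probability is appended
   to the features. One XGBoost gradient-boosted tree ensemble per
   target regresses FEV1 and FVC on the fused 16-dimensional vector.
2. **Sequence regression** (low-dimensional raw-signal path). A
   three-block 1-D convolutional network maps the first 12 s (2400
   samples at 200 Hz) of the expired CO₂ series to (FEV1, FVC).
3. **Error correction.** An improved K-nearest-neighbor regressor
   operates in the 4-D space of the two structures' outputs
   (FEV1_med, FVC_med, FEV1_seq, FVC_seq): the final estimate is the
   unweighted mean of the true (FEV1, FVC) of the K = 5 training
   subjects whose prediction quads are closest in Euclidean distance.
   Quads share units of liters, so no standardization is applied before
   the distance; ties are broken by training index.

Evaluation uses the composite percentage-error family: MPE (maximum
percentage error), MAPE (ε-guarded mean absolute percentage error,
ε = 10⁻⁸) and RMSPE (RMSE divided by the *mean truth* — a cohort-level
denominator, kept deliberately even though a per-sample denominator is
more common). CPE is their mean and ACC = 100 − CPE, both on the 0–100
scale; RMSE and R² are reported alongside. The harness is stratified
10-fold cross-validation (stratified on the obstruction label),
averaged per fold and then over repeats.

## Capnogram feature extraction

The volumetric capnogram (CO₂ vs cumulative expired volume, volume from
trapezoidal integration of expiratory flow with negative excursions
clipped) is segmented into three phases with two least-squares lines:

* **Phase III (alveolar plateau):** fitted over the 60–95 % window of
  total expired volume.
* **Phase II (transitional rise):** fitted over the contiguous run of
  samples whose CO₂ lies between 25 % and 75 % of the end-tidal value
  (mean CO₂ over the last 5 % of expired volume), *and* which sit more
  than 1 mmHg below the extrapolated phase III line. The run starts at
  the first upward crossing of the lower band edge and stops at the
  first sample failing either condition. The line-clearance test
  matters when a steep plateau pushes 75 % of end-tidal above the knee
  CO₂ (common with large phase III slopes): without it, plateau samples
  leak into the rise fit and bias S2 badly low.

Features: C12 is the phase I baseline (mean CO₂ over the first 5 % of
expired volume) and V12 the volume where the phase II line crosses it;
(V23, C23) is the intersection of the two lines; V2 = V23 − V12;
V3 = end-expired volume − V23; S2 and S3 are the line slopes in mmHg/L;
Angle23 = 180° − arctan(S2) + arctan(S3), the interior knee angle
computed on raw mmHg-per-liter slopes without axis renormalization
(this convention lands the cohort mean near 168°). Extraction fails
loudly (`ExtractionError`, carrying the window description) when a
fitting window has fewer than 3 samples, end-tidal CO₂ is ≤ 1 mmHg, or
the fitted S2 is not positive. All windows are configurable through
`ExtractionConfig`.

## Synthetic cohort generator

No real recordings ship with the package, so every experiment runs on
`capnopred.cohort`, a generative model calibrated to the target
population's *marginal* statistics only:

* Demographics: 53.1 % male; age ~ N(56, 14²) truncated to [17, 70];
  height ~ N(166, 9²) cm; weight ~ N(69, 14²) kg; BMI computed.
* Spirometry: FVC = −6.45 + 0.065·height − 0.022·age + 0.6·male +
  N(0, 0.35²) L, floored at 1 L — the intercept is set so the cohort
  mean lands on 3.49 L. FEV1 = ratio·FVC, with ratio ~ N(0.80, 0.05²)
  truncated to (0.70, 0.95] for non-obstructed subjects and
  N(0.60, 0.08²) truncated to (0.30, 0.70) for the obstructed 35 %, so
  the obstruction flag coincides with the strict 0.7 cutoff by
  construction.
* Capnogram geometry: C12, V12, V23 and S2 are drawn at the population
  marginals (truncated normals); S3 is class-conditional (base mean
  4.11, SD 2.55 mmHg/L, ×1.6 when obstructed), numerically calibrated
  so the mixture mean is 5.44 mmHg/L. The expired volume is
  VE = v·FVC with v ~ N(0.78, 0.05²) (×1.12 when obstructed, modelling
  air trapping), giving V3 = VE − V23 a mixture mean near 2.06 L and
  roughly a ×1.2 obstruction inflation. C23, end-tidal CO₂ and Angle23
  are *derived* from the drawn line geometry rather than drawn
  independently: the printed population marginals for C12/V12/V23/S2
  and C23 are mutually inconsistent for straight-line phases, and the
  package resolves the conflict in favor of internal consistency (C23
  ≈ 38 mmHg here). For the same reason the obstruction effect on
  Angle23 follows from the S3 shift through the arctan identity
  (≈ +4° under this angle convention).
* Trace synthesis: the CO₂-vs-volume curve is an idealized three-phase
  shape — flat phase I at C12, *linear* phase II rise with slope S2,
  linear phase III with slope S3 — sampled along a flow profile that
  ramps to a peak proportional to FEV1 (0.45 L/s per L, floored so the
  breath empties within the window) and decays exponentially with the
  time constant that makes the integrated volume equal VE. Gaussian
  noise (σ = 0.3 mmHg) is added to CO₂. Sequences have ≥ 4096 samples
  at 200 Hz. The sharp-kneed linear rise (rather than a smooth
  sigmoidal one) is what makes the zero-noise feature round trip exact:
  the extractor's fitting windows then contain samples of the exact
  generating lines, and every feature is recovered to < 1 %. Internal
  guards (V23 redraw above V12, VE floor keeping V23 ≤ 55 % of VE, V12
  floor keeping the baseline window inside phase I) preserve that
  property across the whole parameter range.

What the generator does **not** emulate: inter-feature correlation
structure beyond the obstruction mixture, sigmoidal phase II/III knees,
cardiogenic oscillations, multi-breath variability, sensor drift, and
the published C23 marginal (see above). Passing tests therefore
demonstrate that the algorithms recover structure the generator puts
in — not clinical performance on real patients.

Determinism: every subject draws from an independent child RNG spawned
from the cohort seed, so cohorts are reproducible and records are
independent.

## Adaptive flow controller

The acquisition system's sampling pump is modelled by an
exponential-smoothing controller: forecast
F̂ = Σ_{j<N} α(1−α)^j F[i−j] (series truncated at the N buffered
values, most-recent first), signed error E = F̂ − F, window-mean error
Ē over the last W errors, multiplicative adaptation
α′ = α(1 + β(E/Ē − 1)), and the sampling command re-smooths the recent
pump flows with α′. Numerical guards added here: when |Ē| < 10⁻⁹ the
ratio is defined as 1 (no update), and α is clamped to (0.01, 0.99) —
the raw update divides by Ē and is otherwise unbounded. With β = 0 the
loop reduces exactly to fixed-parameter smoothing, which the tests use
as an equivalence oracle (on a constant trace F the forecast error is
−F(1−α)^N in closed form).

## Sequence network: architecture and training

Blocks: valid conv (kernel 5, stride 1) → ReLU → max-pool (width 5) →
dropout, with 32/64/32 filters, then flatten and a dense layer to 2
outputs. The length recurrence L → floor((L−4)/5) gives
2400 → 479 → 95 → 18, flatten width 576, and parameter counts
192 / 10,304 / 10,272 / 1,154. Preprocessing: expiration onset is the
first sample above 2 mmHg; the 2400-sample window from onset is taken,
right-padded with the final value when short, and scaled by 1/40 mmHg.

The network and its backpropagation are implemented directly on NumPy
(float32, im2col convolutions) with plain mini-batch SGD: batch 32,
initial learning rate 0.03 decayed ×0.97 per epoch, 100 epochs by
default, MSE loss. Numerical choices that matter at this cohort scale,
all fixed before the evaluation experiments and documented here:

* **Output-bias initialization at the target mean** (and He/Xavier
  initialization elsewhere): the head starts calibrated in liters, so
  SGD spends its budget on signal rather than on the DC offset.
* **Global-norm gradient clipping at 5**: the 0.03 learning rate is
  aggressive for the dense head, whose curvature scales with the
  squared norm of the 576-wide flatten; clipping keeps the early epochs
  bounded.
* **Dropout 0.1** (not higher): with a few hundred training subjects,
  stacked dropout under ReLU/max-pool inflates train-time activations
  relative to eval mode (convexity of ReLU under multiplicative noise),
  and at rate 0.2 the net collapses toward a constant predictor
  (held-out R² for FVC ≈ 0.24 at rate 0.1 vs ≈ 0.07 at rate 0.2 under
  otherwise identical 100-epoch runs). Inference always runs with
  dropout disabled and is deterministic.
* Divergence raises `TrainingDivergedError` naming the epoch;
  predictions are floored at 0.1 L (as are the medical structure's).

## Leakage protocol for the corrector

The KNN stage must be trained on quads that look like test-time quads.
Inside `CombinationPipeline.fit`, the quads for training subjects come
from out-of-fold predictions under an inner stratified k-fold split
(default 5): both structures are refitted on each inner-training part
and predict the held-out part, so no subject's quad is produced by a
model that saw it. The final structures used at test time are fitted on
the full training set. K defaults to 5 (capped at the training size).

## Problem sizes used in the shipped experiments

The package's own evaluation experiments are scaled to desk size: the
end-to-end cross-validation test uses a 300-subject cohort, 10
stratified folds, one repeat, 20 network epochs, a single-point
stage-2 grid and a 2-fold inner split for corrector quads; the
sequence-generalization test trains 240 subjects for 30 epochs.
Full-scale behavior (800 subjects, 100 epochs) was exercised during
development and gives held-out R² ≈ 0.52 / 0.38 (FEV1 / FVC) for the
sequence path alone; the numbers the shipped tests assert are the
scaled-down ones they compute.

## Known limitations

* All performance statements are relative to the synthetic generator;
  none transfer to real patients without real training data.
* The stage-1 classifier's sigmoid probabilities are uncalibrated by
  design (raw-margin sigmoid, not Platt scaling).
* The stage-2 hyperparameter search is a deliberately small
  coarse-to-fine grid (inner 3-fold RMSE, ties to smaller/shallower
  ensembles), not a full optimization.
* RMSPE's cohort-mean denominator makes it scale like a normalized
  RMSE, not a per-subject percentage; MPE is an order statistic and
  dominates CPE at realistic noise levels.
* The CNN is CPU-bound NumPy; it is adequate for thousands of
  subjects, not millions.
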