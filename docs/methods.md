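# Methods

This note records the models, parameter choices and numerical decisions
behind `datprog`, in the order the pipeline runs.

## Synthetic cohort model

The generator emulates a de-novo Parkinson's-disease cohort in which one
latent scalar — motor severity — drives every observed modality.  Each
patient has a trajectory

    s(t) = s0 + rho * t

with baseline severity `s0 ~ Gamma(mean 20, SD 9)` (score units) and annual
progression `rho ~ Normal(2.6625, 1.25)` (score units / year).  Observables
at t ∈ {0, 1, 4} years:

- **Motor score**: `updrs3(t) = clip(s(t) + eps, 0, 132)`,
  `eps ~ Normal(0, 2)`; the Year-4 value is the regression target.
- **SBR** (each of the four striatal subregions, unitless):
  `max(0.05, 2.5 − 0.04 * s(t) + Normal(0, 0.15))` — binding falls as
  severity rises, reflecting dopaminergic terminal loss.
- **Volumes**: four 3D Gaussian blobs at fixed fractional positions
  (caudate heads anterior-medial, putamina posterior-lateral, mirror pairs
  about the mid-sagittal plane; sigma 5.5% of each grid dimension), each
  with peak amplitude equal to its SBR value, over a uniform background of
  0.1, plus `Normal(0, 0.05)` voxel noise clipped at zero.  Default grid
  32×32×16 at 2 mm spacing; realistic DaTscan grids are supported through
  `volume_shape` but are not the default.

The Gamma baseline makes the outcome distribution right-skewed and strictly
positive — matching how observed motor-score distributions look (a long
right tail, minimum well above zero) and keeping percentage errors
well-defined — while preserving the target moments: with the defaults the
Year-4 score has mean 20 + 4·2.6625 = 30.65 and variance
9² + 16·1.25² + 2² ≈ 110 (SD ≈ 10.5).  Demographics are drawn directly:
age `Normal(67.60, 9.96)` clipped to [18, 110], sex male with probability
144/198, years since diagnosis `Uniform(0.4, 2.2)` with symptom onset
0.2–2.5 years earlier, independent of severity.

What the generator does **not** emulate: SPECT physics (attenuation,
scatter, reconstruction), spatial normalization/registration artifacts,
anatomical variability in striatal shape, medication state, non-motor
symptoms, missing visits, or any nonlinear progression.  Passing tests
therefore demonstrate that the pipeline recovers a planted severity signal
from coupled imaging and motor inputs under controlled noise — not
clinical-grade performance on real cohorts.

Everything is a pure function of `CohortSpec` (including its seed); volume
noise seeds are drawn once from the cohort stream, so cohorts are
bit-reproducible.

## Splitting

`split_cohort` permutes records with a seeded generator and assigns
`floor(n·f + 0.5)` records to validation and test each, the remainder to
training.  Half-up rounding is used deliberately: it is deterministic
across platforms and gives 198 → (118, 40, 40) under 60/20/20 and
10 → (6, 2, 2).

## Feature extractors (Stages 1 and 2)

All recurrent/convolutional extractors are implemented in numpy
(`_nn.py`): LSTM with gate order (input, forget, cell, output) and forget
bias 1; convolutional LSTM whose gates are "same"-padded 3D convolutions;
convolutions evaluated by batched real FFTs (zero padding, kernels flipped
so the operation is correlation), chunked over the batch to bound memory.
Initialization is Glorot-uniform from a seeded generator.

A deliberate design choice: **the extractors are fixed random projections.**
Their parameters are drawn once from the extractor seed and never updated;
only the Stage-3 fusion head is trained.  Rationale: (i) with a strongly
informative two-timepoint input, a seed-initialized recurrent network is an
injective-enough nonlinear embedding for a trained head to exploit (the
echo-state / random-features principle); (ii) it makes the feature stage a
pure function, so features are extracted once per cohort and shared across
the eleven members, the ablations, and repeated runs; (iii) it keeps the
full pipeline reproducible to the bit and fast on one CPU.  The named
ImageNet backbones are likewise realized as "stub" networks — small
two-layer convolutional embedders whose weights derive from
(extractor seed, backbone name via CRC-32), distinct per name — because
true pre-trained weights cannot be assumed available offline; requesting
`pretrained=True` raises with instructions rather than silently
substituting.  Backbone frozenness is asserted by parameter checksums
before and after training.

Extractor defaults (all configurable via `ExtractorSpec`): 8 ConvLSTM
filters, 3×3×3 kernels, LSTM hidden width 16, output width 16 per
provenance.  These are desk-scale choices; nothing in the architecture
depends on them.

MIPs are taken along the third (inferior-superior) volume axis, so each
pixel is the brightest voxel of its transaxial column; the axis is an
argument.  Backbone preprocessing rescales each MIP to [0, 1] (a constant
image maps to 0.5), resizes bilinearly to the backbone input size (64×64
default) and replicates the single channel to three.

Stage-2 motor scores are z-scored with the training-partition mean/SD,
which are computed in `FeatureAssembler.fit`/`UpdrsExtractor.fit` and
frozen; validation and test records never touch them.  The same applies to
the continuous clinical covariates (age, years since diagnosis, years since
symptom onset); sex stays a 0/1 indicator (male = 1).

## Fusion head and training (Stage 3)

Architecture: linear(d → 32) → batch-norm → ReLU → dropout(p = 0.5) →
linear(32 → 1).  Batch norm uses eps 1e-5 and running-statistic momentum
0.1; inference always uses the running statistics, so a prediction for one
record is independent of its batch.  Dropout uses inverted scaling and is
active only in training mode.

Training minimizes mean absolute error with Adam (β₁ = 0.9, β₂ = 0.999,
eps 1e-8).  Targets are z-scored with the training-partition mean/SD inside
`train_network`; predictions are mapped back, and the logged per-epoch
train/validation MAE is in raw score units (the mapping is linear, so this
is exact).  Non-finite loss aborts with the epoch and batch rather than
skipping, to keep ensembles complete.  `TrainingConfig` defaults to the
full protocol — 200 epochs, batch 32, dropout 0.5, learning rate 1e-3.

`desk_scale_config` (30 epochs, learning rate 2e-2) is used by the tests
and the acceptance script.  The learning rate follows from Adam's
normalized updates: each step moves a parameter by at most ≈ the learning
rate, and 30 epochs × 4 batches = 120 updates must traverse the O(1) scale
of the standardized target, so lr ≈ 1/120 is the smallest rate that can
converge at this budget.

Seeding: member networks use `master_seed + combo.id` (ids 1–11); the four
ablation networks use `master_seed + 100 + ablation.id`, keeping every
model independent yet derived from one integer.  Grid search evaluates the
full Cartesian product in the given key order and keeps the first
strictly-best validation MAE (lexicographic tie-break).

The ensemble is the unweighted mean of the eleven member predictions.  By
convexity of squaring, its per-record squared error never exceeds the mean
of the members' squared errors; this identity is asserted on every
evaluation run.

## Evaluation protocol

- **MAPE/MAE/MSE**: per-case values `100|e|/y`, `|e|`, `e²` with
  `e = y − ŷ`; the estimate is the mean and the 95% CI a two-sided
  t-interval on the per-case mean.  The t-interval was chosen because it is
  the simplest method consistent with symmetric intervals around the point
  estimate.  Any observed score ≤ 0 makes MAPE undefined; it is reported as
  absent with a reason while MAE/MSE are still returned.
- **Pearson r** with the t-transform p-value (n − 2 df).
- **OLS** of predicted (ordinate) on observed (abscissa), matching the
  predicted-versus-observed orientation of the scatter plots; 95%
  confidence (mean-response) and prediction (adds residual variance) bands
  on a grid, via statsmodels.
- **Bland–Altman**: differences `d = observed − predicted`; bias = mean(d)
  with 95% t CI; limits of agreement mean ± 1.96·s with CIs from the
  standard limit-variance approximation 3s²/n (t quantile, n − 1 df);
  one-sample t-test of zero bias; Shapiro–Wilk on d.  Constant differences
  collapse the limits to the mean and flag the report degenerate instead of
  producing NaNs.
- **Failure analysis**: cases with per-case MAPE above mean + 2·SD
  (sample SD); the threshold is reported alongside the flags.
- **Model comparison**: per-case difference of squared errors
  `(a − y)² − (b − y)²` (positive mean ⇒ model a worse), mean with 95% t
  CI, paired two-tailed t-test.

All closed-form statistics delegate to scipy/statsmodels; the test suite
checks each against independent direct-formula computations to 1e-10.

## Experiments

For one master seed, all three experiments share a single cohort, split and
extractor set.  The ensemble experiment trains the eleven members and
evaluates their average.  The input-ablation experiment trains four fresh
networks (all inputs; no clinical; no DaTscan; no MDS-UPDRS-III), where the
imaging block is the ConvLSTM features only, and compares each to the
ensemble by difference of squared errors.  The feature-combination
experiment evaluates the eleven members individually against their own
ensemble and emits a summary table (MAPE, MAE, MSE, r, R² with CIs).

## Problem sizes

The package's test and acceptance runs use the default cohort (n = 198,
32×32×16 volumes, stub backbones) with the desk-scale training
configuration; unit tests use 40-patient cohorts with 12×12×8 volumes and
narrower extractors.  Generator-moment checks use n = 2000.  These sizes
are the package's choices for a single-CPU workflow; paper-scale settings
(full DaTscan grids, 200 epochs, true pre-trained backbones through an
external runtime) remain reachable through configuration.

## Known limitations

- Fixed random-projection extractors trade representational adaptivity for
  determinism and speed; an end-to-end-trained ConvLSTM could extract
  sharper imaging features on real data.
- The stub backbones share only the interface of the named ImageNet
  architectures, not their inductive biases; results involving individual
  backbone columns are structural, not architectural, comparisons.
- The generator's linear severity trajectory and Gaussian blob anatomy are
  idealizations; no claim transfers to real DaTscan cohorts without
  retraining and revalidation.
- No early stopping (a fixed epoch budget is part of the protocol), no
  bootstrap CIs, no non-parametric agreement statistics, no stacked
  meta-learner over the ensemble.
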