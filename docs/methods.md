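# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `pdprognosis`, together with what the synthetic
validation does and does not establish.

## Synthetic cohort model

The generator emulates a de-novo Parkinson cohort at the level of summary
structure, not imaging physics.  Per subject *i*:

* a scalar disease-severity latent `s_i ~ N(0, 1)` (patients; controls are
  fixed at `s = 0` and excluded from modelling by default);
* DBM region *r*: `x_ir = mu_r + gamma * s_i + sigma * eps`, with template
  means `mu_r ~ N(1, 0.05)` (Jacobian-determinant scale), severity loading
  `gamma = 0.08` and measurement noise `sigma = 0.3`.  Standardised
  deviations `z_ir = (x_ir − mu_r) / sqrt(gamma² + sigma²)` carry the
  signal;
* year-*t* outcome: `score_t = center_t ± scale * (W[:, t]·z_i + eta)`,
  where `W` is the region × year effect matrix per modality, `eta ~ N(0, 1)`
  is score noise, and the sign makes MoCA decrease and UPDRS increase with
  atrophy signal.  Scores are rounded, clipped to the instrument range, and
  thresholded (MoCA 26/27, UPDRS-III 32/33) into the binary categories;
* non-imaging covariates (age, sex, disease duration, baseline MoCA and
  UPDRS-III, Hoehn–Yahr, CSF α-synuclein and amyloid-β, four SBR values)
  are Gaussian around published cohort summary statistics (age 59.8 ± 9.5,
  baseline MoCA 27.5 ± 2.1, UPDRS-III 20.6 ± 8.6, duration 6.26 ± 6.25
  months) with mild severity loadings;
* missingness is MCAR at a default cell rate of 0.5% — enough to exercise
  the "more than two missing features" exclusion rule and the
  training-median imputation, nothing more.

**Why gamma = 0.08.**  The shared-severity loading controls how strongly
*every* region correlates with *every* outcome.  At 0.08 the marginal
region–score rank correlations and the per-year count of screen-passing
regions (a handful to ~15, |ρ| ≈ 0.2–0.35) match what published baseline
screening tables of this kind display, while a planted dominant region
(weight 0.9) remains identifiable.  Larger loadings flood the screen with
severity proxies and smear saliency across collinear regions.

**Year-varying effects.**  The default effect matrix gives each modality
one dominant region (standardised weight 0.9) in years 1–2 that switches
identity in years 3–4, plus small 0.15 background weights.  This planted
reordering is the ground truth against which the saliency pipeline is
validated — something no real cohort can provide.  The default region
labels echo structures prominent in the Parkinson literature (Putamen,
Substantia Nigra, Pallidum, Caudate); they are labels only and carry no
computation.

**Score centres** drift mildly toward impairment across years (MoCA 26.9 →
26.0; UPDRS 31.5 → 33.0) so both categories stay populated at every
horizon; with noise the class split is roughly 45–55%.

What the generator does *not* emulate: realistic marginal DBM
distributions (a Gaussian convenience), informative missingness,
site/rater effects, non-linear disease trajectories, or label noise from
clinician scoring.  Passing tests therefore demonstrate that the pipeline
recovers structure *of the planted kind* at realistic n, not that it would
achieve any particular accuracy on real data.

## Preprocessing

Subjects missing more than two input features are excluded (boundary: two
missing is retained).  Remaining gaps are filled with medians computed on
training subjects only.  Default scaling is min–max to [0, 1] fitted on the
training split — the autoencoder's decoder is a logistic sigmoid with range
(0, 1), so reconstruction targets must live there; a z-score mode exists
for other uses.  Constant training features map to 0.5 by convention.  The
positive class for sensitivity is the impaired category (configurable).

## Screening

Spearman's ρ is the Pearson correlation of mid-ranks (average ranks on
ties); with no ties it equals `1 − 6Σd²/(n(n²−1))`.  Two-sided p-values use
`t = ρ·sqrt((n−2)/(1−ρ²))` on n−2 degrees of freedom — accurate at n ≈ 116;
an exact permutation mode (n ≤ 10) serves as the small-sample oracle.
Constant inputs raise rather than silently returning 0.  The screen keeps
candidates with p < 0.05, no multiplicity correction, against the **raw**
year-t score (not the binary label).  By default only DBM regions are
screened and other baseline covariates are appended unscreened; a switch
screens everything.  Screening runs inside each training split by default
(leakage-safe); whole-sample screening is available as a flag for
comparison with single-shot analyses.

## Sparse autoencoder

Cost per layer: `(1/N) Σ_n ‖x_n − x̂_n‖² + λ·½(ΣW1² + ΣW2²) +
β·Σ_i KL(ρ‖ρ̂_i)`, biases unpenalised, `ρ̂_i` the batch-mean activation of
hidden unit *i*, clipped to [1e-8, 1−1e-8] to avoid log singularities
(saturation can instead raise, on request).  The per-sample-sum/
per-feature-raw averaging convention is one of several reasonable
"adjusted MSE" readings; what matters is that cost and analytic gradient
use the same convention, which the finite-difference tests enforce.

Weights initialise from N(0, 0.01²), biases at zero, per-layer seeds, so
training is fully deterministic.  Defaults λ = 0.004, β = 4, ρ = 0.10 sit
mid-range of the sweeps the method was developed with (λ ∈ [0.001, 0.009],
β ∈ [2, 6], ρ ∈ [0.05, 0.20]); values outside those ranges warn but run.
A one-variable-at-a-time sequential grid search on validation accuracy
(`sequential_hyperparameter_search`) is provided; the evaluation pipeline
uses the fixed mid-range defaults to keep repeated-split runs cheap and
reproducible.

Stacking is greedy (layer 2 trains on layer 1's codes); the SoftMax head
trains on the final codes by cross-entropy; then the encoder chain + head
is fine-tuned end-to-end on cross-entropy with decoders discarded and
regularisers dropped.  Since fine-tuning starts from the greedy solution
and the optimiser never accepts cost increases, the fine-tuned training
cost cannot exceed the pre-fine-tuning cost.

### Scaled conjugate gradient

Møller's SCG: line-search-free conjugate directions with a one-sided
finite-difference curvature estimate (σ₀ = 1e-4) and Levenberg–Marquardt
damping adapted from the comparison ratio.  Full batch — at n ≈ 116 this is
exact and deterministic.  Two numerical choices beyond the textbook
algorithm:

* a non-finite trial cost is treated as a failed step (damping grows)
  rather than a crash; a non-finite cost at the *current* iterate aborts
  with a diagnostic;
* when the cost difference of a trial step falls below the double-precision
  rounding floor (|f − f'| ≤ 4·eps·(|f|+|f'|)), the comparison ratio is
  taken as 1 and the model step trusted: near an optimum the cost change
  underflows long before the gradient does, and without this guard the
  damping explodes on comparison noise and terminal convergence stalls at
  ~1e-7 instead of reaching 1e-9 on benchmark quadratics.

### Small-input caveat

On inputs of ~10 features the KL penalty admits a constant-activation
solution (all codes equal to ρ) that is a saddle of the joint objective;
deterministic SCG from tiny initial weights converges into it, the codes
carry no variance, and the downstream softmax gradient vanishes, blocking
fine-tuning.  With the ~80-dimensional cohorts the penalty behaves as
intended (mean activation pinned at ρ, variance preserved).  The
interaction study below therefore disables the pretraining regularisers
(β = λ = 0); this is a property of the penalty at small input dimension,
not a tuning knob.

## Evaluation

"Five-fold cross-validation" is implemented as five independent random
stratified 80/20 splits — matching the operational description of the
protocol ("randomly split the data 5 different ways"); a conventional
k-fold partition is easy to build from `SplitPlan` if wanted.
Stratification keeps class proportions within one subject of proportional;
splits whose training half is single-class are redrawn (≤ 20 attempts).
The logistic comparator is Newton–Raphson IRLS on cross-entropy with an
optional ridge (default 1e-3 inside the pipeline for numerical stability
with collinear screened features; 0 for the bare operation), capped at 100
iterations so separable data terminate.  Probability ties (p = 0.5) predict
the positive class, deterministically.  Accuracy, sensitivity and
specificity come from explicit confusion counts.

## Saliency

Perturbation is applied to **raw** DBM values (×1.10 or ×1.20) before the
model's frozen training scaler — "increase the region's DBM value" refers
to the measured quantity, and freezing the scaler keeps the original and
perturbed predictions on the same pipeline.  δ(j) is the Frobenius norm of
the prediction-matrix shift over the full modelling cohort (a test-only
subject set is a flag).  Screened-out regions get δ = 0 rather than being
omitted, so every profile covers all 78 regions.  Shares are
L1-normalised; the salient flag uses share > 0.04 (the "4%" threshold is
read as *relative* saliency); ranks break ties by region name.  The
reported profile averages δ over the five split models by default —
single-model profiles are noticeably noisier (a single stack occasionally
concentrates all its sensitivity on one spurious region) and per-split
profiles remain available.  The reordering report tabulates shares and
ranks per year and records each region's earliest salient year.

## Validation scale

The end-to-end checks run at the cohort's natural size (n = 116 patients,
78 regions): saliency recovery over 50 generator seeds × 4 years with
5-split-averaged profiles; the screening calibration over ≥ 1,500 null
feature–outcome pairs; the permutation-null classifier check over 20 seeds;
the interaction (nonlinearity) study on 20 seeds of a 6-region, 200-patient
cohort with a pure two-region product effect, where the autoencoder's mean
out-of-sample accuracy exceeds logistic regression's (~0.57 vs ~0.49 —
partial, not perfect, XOR learning at this sample size).  These sizes give
stable Monte-Carlo estimates while keeping a full suite run to a few
minutes.

## Known limitations

* The autoencoder brings no accuracy advantage over logistic regression
  when planted effects are linear — expected, and observed in the default
  cohort; its advantage appears only under interaction structure.
* Saliency is a local, model-mediated measure: collinear regions share
  credit, and a region can be salient through correlation with a causal
  one.  The planted-recovery tests quantify this at the chosen generator
  settings only.
* The exact-permutation p-value is factorial in n and refuses n > 10.
* Depth beyond two encoder layers is configurable but untested; no
  minibatching, no GPU, no denoising/variational variants.
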