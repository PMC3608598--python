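# Methods

## Problem and model

metalinprog classifies samples from metagenomic feature-count tables
(OTUs, taxa, pathways) and simultaneously selects the features that drive
the classification.  Counts for sample *i* form a row *x<sub>i</sub>* of
the n × m matrix **X**; each sample carries a phenotype label from *c*
categories.

**Binary phenotypes (c = 2).**  The classifier is the linear rule
f(x̃) = β₀ + βᵀx̃ on the transformed abundances x̃, trained by minimizing

    Σᵢ max(0, 1 − yᵢ f(x̃ᵢ)) + λ ‖β‖₁ ,   y ∈ {−1, +1},

the soft-margin hinge loss plus an L1 penalty.  The intercept is not
penalized.  The L1 penalty drives most coefficients to exactly zero, so
the support of β is the selected feature set.

**Multiclass phenotypes (c > 2).**  Labels are one-against-rest encoded
into K = c − 1 sign problems (the last class is the reference; its
parameters are pinned at zero for identifiability under the sum-to-one
probability constraint).  The K linear classifiers (β₀ₖ, βₖ) are trained
*jointly*:

    Σₖ Σᵢ max(0, 1 − y
    ᵢₖ fₖ(x̃ᵢ)) + λ Σⱼ maxₖ |βⱼₖ| .

The penalty is the L∞,1 mixed norm of the m × K coefficient matrix **B**:
an L∞ norm across the subproblems of each feature row, summed (L1) over
features.  Once a feature's largest coefficient is paid for, the other
subproblems may use it for free — so all K classifiers share one sparse
feature set, instead of each one-vs-rest classifier choosing its own.
Class probabilities use the multinomial-logit form
pₖ = exp(fₖ)/Σₗ exp(fₗ) with the reference score fixed at 0 (max-shifted
for overflow safety), and the predicted class is the argmax, ties to the
earliest class.

## Linear programming

Both problems are linear programs.  Free parameters are split into
nonnegative parts (β = u − v, β₀ = b⁺ − b⁻), hinge terms become slack
variables ξ bounded by the margin constraints, and the multiclass row
maximum becomes a variable tⱼ with box constraints −tⱼ ≤ βⱼₖ ≤ tⱼ.  At
any optimum ξ equals the hinge residual exactly and tⱼ = maxₖ |βⱼₖ|
(anything larger would cost more); both identities are enforced by test.
The binary LP has 2m + 2 + n variables and n constraints; the multiclass
LP has 2mK + 2K + nK + m variables and nK + 2mK constraints.

LPs are solved through SciPy's HiGHS interface.  The default backend is
the interior-point variant (`highs-ipm`, with crossover), which on the
tall sparse multiclass programs is several times faster than dual
simplex; `highs` and `highs-ds` are selectable alternatives, and every
optimal point is independently re-checked for feasibility (tolerance
1e−6) and objective consistency (relative 1e−8) before being accepted.
Interior-point solutions are only approximately sparse, so coefficients
below 1e−6 · max(1, max |β|) are reported as zero (the "snap" threshold
used by `selected_features`).

## Preprocessing

1. **Relative abundance**: pᵢⱼ = xᵢⱼ / Σⱼ xᵢⱼ removes sequencing-depth
   differences.  All-zero samples are an error, never silently dropped.
2. **Variance stabilization**: proportions have mean-dependent variance.
   The square-root transform √p and the arcsine transform arcsin(√p)
   (radians, mapping [0, 1] to [0, π/2]) are both available.  Bartlett's
   chi-squared test — computed with samples as groups, each sample's m
   feature values as observations, df = n − 1 — drives the advisory
   `choose_transform` rule: no transform under homogeneity (p ≥ α,
   default α = 0.05); square root when heterogeneous data occupy a single
   band ([0, 0.3], or all nonzero values ≥ 0.7, zeros being structural);
   arcsine otherwise.  The default pipeline applies the arcsine transform
   unconditionally, the safe choice for proportion data spanning the
   whole range, and records the transform in the fitted model so
   prediction re-applies it; a new sample's proportions use its own row
   sum only.

Grouping Bartlett's test by sample (rather than by phenotype class) is a
deliberate reading of the preprocessing recipe this package implements;
the statistic is scale-free either way, and the test is advisory only.

## Choosing λ

λ trades training fit against sparsity: too small overfits with little
sparsity, too large empties the model.  `cv_lambda` picks it by
stratified k-fold cross-validation (k = 10 default; k = n gives
leave-one-out) minimizing held-out misclassification, ties resolved
toward the *largest* λ — the sparser model — in keeping with the
method's parsimony goal.

**Normalized λ scale.**  The LP objective is a raw sum of n slacks
against a raw sum over m features, so the useful range of the raw weight
shifts with the data size (on arcsine-transformed 1000-feature tables it
is ~0.05–0.5).  The selection layer therefore expresses the user-facing
grid on a size-normalized scale: the LP weight is λ · n/m.  This makes
one ladder — default {0.5, 1, 2, …, 10, 15, 20}, the simulation study
uses {1, …, 10} — meaningful across problem sizes.  `fit_binary` /
`fit_multiclass` always take the raw LP weight; `fit_model(...,
normalized=True)` and everything above it use the normalized scale.

## Evaluation protocol

`repeated_split_eval` repeats R times: stratified random split into
training/test (default 50/50), λ selected on the training part only
(`"cv"` re-selects each repeat; `"cv_once"` selects on the first repeat
and reuses the value), fit, record the selected features, test
misclassification and test AUC.  The per-feature *relevance count* —
how many repeats selected the feature — is the stability measure a
practitioner ranks features by.  Binary AUC is the Mann-Whitney
probability (ties one half), computed from a threshold-sweep ROC curve
whose trapezoidal area equals it; the multiclass summary is the
macro-averaged one-vs-rest AUC over the probability columns, a
deliberate choice documented here because the multiclass "AUC" of a
c-class problem has no single canonical definition.

## Synthetic data

`simdata` emulates a planted-feature study on overdispersed counts.
Every count is Poisson with a Gamma-distributed rate (mean 100, variance
1000 ⇒ shape 10, scale 10), drawn fresh per sample-feature cell, so
background features are marginally negative binomial with mean 100 and
variance 1100 in every class.  The first `n_relevant` features carry the
signal, in one of two layouts.  In the `uniform` layout (default) every
planted feature multiplies its Gamma mean in class g by `effect[g]`.
In the `rotated` layout planted feature j uses `effect[(g + j) mod c]`,
giving each planted feature its own class profile.  The rotation matters
for c > 2: if all planted features shared one monotone profile the
latent signal would be one-dimensional and the middle classes could
never be separated one-vs-rest (macro AUC saturates near 0.75 regardless
of effect size); rotated profiles make the planted set jointly
class-separating, which is what "relevant features with different
distributions" has to mean for a multiclass design whose published AUC
is near 0.97.  An all-equal effect vector plants no signal and serves as
the null control.  A `rate_sharing="feature"` variant draws one rate per
feature (shared across samples) instead; it produces far cleaner
within-class counts (pure Poisson noise) and is kept as a contrast, not
the default, because a single feature then separates the classes
perfectly and the study degenerates.

**Default effects** are calibrated so that the reference protocol run on
this generator attains its published operating point — near-perfect
binary test AUC with ≈ 5 of the planted features selected, and high
four-class macro AUC with the same sparse joint support: binary
(1, 2.5) uniform, four-class (1, 2, 4, 8) rotated.  Under this
calibration the cross-validated λ lands mid-grid (≈ 3–8 binary, 6–7
four-class), consistent with the mid-grid optima such a study reports.
The calibration is a property of this generator, not of the method;
users probing weaker signals should lower the multipliers.  One
published property is *not* reproduced robustly: with the rule that ties
are broken toward the sparsest model, binary repeats whose selected λ
lands at the sparse end of the zero-error plateau drop one or two of
the (partially redundant) planted features, so per-feature recovery
runs 75–100% rather than uniformly ≥ 95%; the four-class design, whose
rotated features are not redundant, recovers all five essentially
always.

What the generator does *not* emulate: compositional closure effects
beyond the shared row normalization, zero inflation, phylogenetic or
co-occurrence correlation between taxa, and uneven library sizes.
Passing the simulation study therefore demonstrates correct mechanics
and calibrated statistical behavior of the estimator, not robustness to
those real-data phenomena.

## Scaled-down study sizes

The packaged simulation study (`run_simulation_study`, also what
`scripts/acceptance.py` runs) uses 20 repeats with a fresh simulated
dataset per repeat and stratified 5-fold (binary) or 3-fold
(four-class) cross-validation for λ on the training half, standing in
for leave-one-out selection.  For binary designs λ is re-selected on
every repeat (`lam_mode="cv_each"`): selection is cheap there, and
averaging twenty selections keeps the model-size estimate from being
dominated by a single CV draw.  For multiclass designs λ is selected
once on the first repeat's training half and reused
(`lam_mode="cv_once"`): the joint LP makes per-repeat re-selection an
order of magnitude costlier, and the selected value is insensitive
across repeats.  These are the package's own problem sizes, chosen to
keep a full two-design run in the low minutes on one CPU; `repeats`,
`folds`, `lam_grid` and `lam_mode` are all parameters.

## Numerical choices and degenerate inputs

- Solver feasibility re-check 1e−6; objective identity 1e−8 (relative);
  coefficient snap 1e−6 (relative to the largest magnitude).
- Binary ties at score exactly 0 predict +1; multiclass probability ties
  predict the earliest class.  Any fixed rule would do; this one is
  documented and deterministic.
- Binary problems use the dedicated binary LP (half the variables of the
  c = 2 joint LP); the two formulations provably share their optimum and
  the equivalence is enforced by test.
- Reference class defaults to the last class in first-appearance order
  and is configurable.
- Single-class inputs, empty λ grids, folds exceeding the smallest class,
  all-zero samples, zero within-sample variance (Bartlett) and
  feature-name mismatches at prediction time are all hard errors with
  the offending item named.
- All randomness (simulation, splits, fold shuffling) flows from
  explicit integer seeds; equal seeds give bit-identical reports.

## Known limitations

- LP sizes grow as O(mK) variables; tables beyond ~10⁴ features or many
  classes will be slow with the bundled dense-free but single-threaded
  backends.
- No class weighting: strongly unbalanced designs push the intercept
  rather than the coefficients.
- The multiclass probability transform is the fixed softmax link; no
  calibration beyond it.
- Relevance counts are reported without a significance calibration
  (no stability-selection error control).
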