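# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator, and the design decisions taken where the
procedure was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing

Beta values (fraction methylated, in [0, 1]) are processed per probe over
the full sample, before any train/test splitting:

1. **Winsorization (3×IQR).** With Q1, Q3 the first/third quartiles and
   IQR = Q3 − Q1, values above Q3 + k·IQR or below Q1 − k·IQR (k = 3 by
   default) are replaced by the *most extreme observation still inside the
   fence* — not by the fence value itself. Quartiles use linear
   interpolation between order statistics (the default convention of
   mainstream statistical environments). The operation is idempotent and
   never widens a probe's range; constant probes pass through unchanged. A
   probe whose every value would fall outside the fences is degenerate and
   raises.
2. **Autosomal filtering.** Only probes on chromosomes 1–22 are retained,
   for consistent interpretation between sexes; X/Y probes are flagged in
   the manifest and dropped.
3. **Standardization.** Each probe is z-scored (mean 0, sample SD 1 with
   the n − 1 denominator). Probes that are constant after winsorization
   have no defined z-score and are dropped with a logged count.

## Similarity matrix

With **X** the n × p matrix of methylation z-scores,

    M = XX' / mean(diag(XX')).

Dividing by the mean diagonal fixes the average diagonal at exactly 1. No
per-pair feature-count normalization is applied — the scaling is a single
global constant, which also makes M invariant to rescaling all columns of
X by a common factor. M is computed once on the full sample and held fixed
across cross-validation splits. This mirrors the original procedure's
information flow (the similarity structure, though not the outcome, is
shared between train and test) and is documented as such rather than
changed: recomputing M per split would alter the estimand.

A blocked accumulation over probe chunks is available for very wide
matrices; it is algebraically identical to the naive product.

A note on a structural fact used by the tests: because z-scored columns
sum to zero, the mean off-diagonal entry of M is exactly −1/(n − 1); the
"off-diagonal entries concentrate near zero" behaviour holds for i.i.d.
(not empirically centered) features.

## Mixed model and REML

For a training set of n samples,

    y = W beta + g + b + e,
    g ~ N(0, sigma2_m M),   b ~ N(0, sigma2_batch Z Z'),   e ~ N(0, sigma2_e I),

where W contains an intercept and the encoded covariates (categoricals
dummy-coded dropping a reference level; compositional covariates such as
cell proportions must be supplied with one component omitted), and Z is
the batch indicator matrix. Batch enters the baseline and methylation
models identically, as a random intercept.

The restricted log-likelihood (up to a constant) is

    l(theta) = -1/2 [ log|V| + log|W' V^-1 W| + y' P y ],
    V = sigma2_m M + sigma2_batch Z Z' + sigma2_e I,

with P the usual REML projection. **Numerics:** all evaluations are done
in the eigenbasis of M, where sigma2_m D + sigma2_e I is diagonal and the
batch term has rank B (number of batch levels), handled by a Woodbury
identity. One n × n eigendecomposition per training set then makes every
REML iteration O(n²·B), which is what keeps 100-split cross-validation at
n in the hundreds cheap. Negative eigenvalues of M arising from round-off
are clipped at zero.

**Optimizer.** Average-information (AI) REML: the update solves
AI·Δ = score, with step-halving if the proposal leaves the feasible region
or decreases the likelihood, and an EM step as fallback when no AI step is
acceptable. Starting values are equal thirds of the phenotypic variance.
Convergence is declared when the relative log-likelihood change drops
below 1e-8 (max 100 iterations); non-convergence returns the current point
with `converged=False` and a warning. Components are constrained
non-negative by clamping at zero with an active set: a clamped component
is released if its score at the boundary turns positive, and boundary
solutions are reported in `on_boundary`. A near-singular AI matrix at the
solution (e.g. M ≈ I making sigma2_m and sigma2_e jointly unidentifiable)
triggers a flat-likelihood warning.

**BLUP prediction.** For held-out samples,

    g_test = sigma2_m M_cross V^-1 (y - W beta_hat),

added to W_test·beta_hat, plus the batch BLUP for test samples whose batch
level occurred in training (unseen levels contribute 0 — the standard
convention; the contribution can be switched off via
`include_batch_blup=False`, since whether the original analysis included
it is not determinable and the default here is to include it).

## Cross-validation, imputation and pooling

Per split (default 100 splits, training fraction 0.9, train size rounded
half-to-even): baseline and methylation models are fitted on the same
training samples; test-set R² is the squared Pearson correlation between
BLUP predictions and observed outcomes (constant predictions give R² = 0
with a warning); ΔR² = R²_methylation − R²_baseline is computed *per
split* and only then aggregated into its mean and sample SD (SD_CV).
Negative per-split ΔR² values are retained. Per-split differencing is
deliberate: pooled ΔR² is not the difference of pooled R²s, and only the
per-split version reproduces two-cohort pooled deltas from cohort-level
columns. Splits that fail outright (numerical error) are logged and
excluded from aggregation; non-converged but finite fits are kept.

**Multiple imputation.** Missing covariate/outcome cells are completed by
a compact chained-equations implementation (default m = 10 imputations,
30 cycles): predictive mean matching with 5 donors for continuous
variables, logistic draws for binary, multinomial draws for multi-level
categoricals; predictors are the other covariate and outcome variables,
never the methylation matrix. Initialization draws from observed
marginals; variables are visited in order of increasing missingness.
Cell-proportion columns of imputed rows are renormalized so the
composition sums to the typical observed total, rescaling only the imputed
cells so observed values are never altered. This is a simplified
reimplementation of the chained-equations idea, adequate for the missing
data the generator produces; it has no congeniality diagnostics, passive
imputation or parameter-uncertainty draws.

**Pooling.** Across imputations, Rubin's rule with total variance
T = W̄ + (1 + 1/m)·B, where the within-imputation variance is the CV
sample variance of per-split estimates (SD_CV²), not a squared standard
error — this reading is required for the cohort-level SDs to reproduce
published two-cohort pooled SDs through the next stage. Across cohorts,
inverse-variance weighting: weights 1/SD², pooled SD = sqrt(1/Σw). Pooling
is applied independently to ΔR², baseline R² and methylation R².

## Methylation-correlated blocks

Probes are sorted by (chromosome, position); a greedy left-to-right scan
extends the current block to the next probe iff the Pearson correlation
between the block's **last-added** probe and the candidate is ≥ r
(default 0.3) *and* the positional gap is ≤ 1000 bp; otherwise a new block
starts. Blocks never span chromosomes. Size-1 blocks are the independent
CpGs (r < 0.3). Correlations are computed on winsorized beta values
(pre-standardization), consistent with block construction on methylation
levels. Each block is summarized by the per-sample mean beta; the reduced
feature set (blocks + singletons) then flows through standardization and
the similarity matrix as usual. The chaining rule and the choice of
correlation scale are conventions — "neighboring" admits several readings
— fixed here so results are exactly reproducible.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, with known
ground truth:

* **Methylation.** Latent per-probe normals with AR(1) correlation (default
  block size 10, rho = 0.7) inside blocks laid along 22 chromosomes (small
  gaps inside blocks, large gaps between), mapped through a logistic link
  with per-probe baseline and scale into strictly-(0,1) betas. Methylation
  is always complete.
* **Outcome.** A poly-epigenetic score over a random 1% of probes
  (standard-normal effects on standardized betas), a batch random
  intercept (default 6 levels), a covariate linear predictor and Gaussian
  noise. Each component is empirically standardized before scaling, so the
  realised variance decomposition matches the requested fractions up to
  small sample cross-correlations; the true per-sample components are
  retained on the `Cohort` object for oracles.
* **Covariates.** Sex ~ Bernoulli(0.5); maternal age ~ N(30, 4.3²);
  smoking ~ Bernoulli(0.13); 3-level education; cord-blood cell-type
  proportions from a Dirichlet with realistic means and per-type SDs of a
  few percent — giving the full covariate set realistic collinearity.
* **Missingness.** MCAR by default on outcome/covariates (never batch); an
  MAR option keys missingness to always-observed maternal age.
* **Randomness.** Independent sub-streams (methylation / covariates /
  outcome / missingness, and per cohort) spawned from one master seed.

What the generator does *not* emulate: probe-level measurement error of
the array chemistry, genetic confounding, cell-type-driven methylation
structure, or non-Gaussian outcomes. Passing tests therefore demonstrate
correctness of the estimation machinery under the model's own assumptions,
not robustness to the full messiness of real cohort data.

## Problem sizes used in tests and the acceptance script

Simulation checks use cohorts of n = 300–800 with p = 500–2000 probes and
8–20 CV splits — large enough for stable Monte-Carlo behaviour (variance-
component recovery is checked at n = 800, p = 2000 with 12–20 replicates
per setting) while keeping the default suite fast. At these sizes the
out-of-sample ΔR² is systematically below the simulated variance share:
BLUP prediction accuracy is limited by n relative to the number of
effective methylation features, and with no signal the REML estimate sits
on the sigma2_m = 0 boundary in most splits, collapsing ΔR² spread toward
zero. Both attenuation effects are real properties of the estimator at
cohort-scale n (not artifacts), and the suite asserts them qualitatively:
null traits give |mean ΔR²| < 0.02 with small SD, and mean ΔR² is strictly
monotone in the simulated signal.

## Known limitations

* Single similarity matrix only: no joint genetic + methylation models, no
  interaction matrices.
* No standard errors or likelihood-ratio tests for variance components;
  uncertainty is expressed via the cross-validation distribution, which is
  the estimand of interest here.
* The REML boundary at sigma2_m = 0 biases small-sample CV estimates of
  weak signals toward zero; estimates for weakly associated outcomes at
  n in the hundreds should be read as lower bounds.
* The imputation module targets the generator's missingness patterns; for
  complex real-data missingness a full-featured imputation framework is
  preferable upstream, feeding completed tables into `run_cv`.
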