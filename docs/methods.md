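# Methods

`neuropls` implements the statistical core of a multi-site brain–cognition
biomarker analysis in late-life treatment-resistant depression: latent-variable
(PLS) models linking brain-feature blocks to a cognitive battery, with
permutation and bootstrap inference, empirical-Bayes site harmonization,
leave-one-site-out generalizability, and stability-selected elastic-net
prediction of treatment remission. This note records the models, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
validation does and does not establish.

## 1. PLS regression engine

Given a standardized feature block `X` (participants × p) and standardized
cognition block `Y` (participants × q), each latent variable (LV) is a pair of
directions maximizing cross-block covariance. The implementation is NIPALS in
*regression mode*: per component the weight vector `w` converges to the
dominant singular direction of the cross-covariance `X'Y` (power iteration in
the cheaper of the two dimensions), scores are `t = Xw`, X-loadings
`p = X't/t't`, Y-loadings `q = Y't/t't`, and only `X` is deflated
(`X ← X − tp'`). Because successive scores are orthogonal and Y-loadings are
taken against the original `Y`, per-component fractions of Y-variance
explained are additive. The X→Y coefficient matrix is
`B = W(P'W)⁻¹Q'`, which maps standardized held-out features to predicted
standardized cognition without refitting.

Design choices worth noting:

- **Variant.** NIPALS regression-mode was chosen over SIMPLS; the two agree
  exactly on the first component and differ negligibly beyond it at these
  data scales. The implementation is cross-checked in the test suite against
  scikit-learn's `PLSRegression` (predictions) and against a brute-force SVD
  of `X'Y` (first-component weights).
- **Sign convention.** Each component is flipped so its largest-magnitude
  X-weight is positive, making fits reproducible and bootstrap alignment
  well-defined.
- **Rank guards.** `n_components` may not exceed `min(n−1, p)`; a block that
  deflates to numerical rank 0 raises rather than returning garbage.
- **Standardization contract.** `fit_pls` requires column-centered input
  (tolerance 1e−6 on means) and raises otherwise; standardization parameters
  are always carried by the caller (`zscore_columns` returns them) so held-out
  data are standardized with training parameters.

### Inference

**Model significance** is assessed by permuting participants' rows of `Y`
(n_perm default 5000 at publication scale; reduced counts are used in
desk-scale runs), refitting, and recording the total fraction of Y-variance
explained. The p-value uses the add-one correction
`p = (1 + #{null ≥ observed})/(n_perm + 1)`, which is conservative and never
zero. The permutation null mean is also reported as a bias estimate: in-sample
PLS variance explained is optimistic (the weights are chosen on the same
sample), and `observed − null_mean` is an approximately debiased effect-size
estimate used in the pipeline report.

**Number of components** is chosen by a sequential permutation rule: the
dominant singular value of the residual cross-covariance is compared with its
permutation null; a component is retained at p ≤ α (default 0.05), both blocks
are deflated, and the test repeats. On simulated data the rule returns 0
components on null data, 1 for a single planted factor, and 2 for two
orthogonal factors in the large majority of runs. This rule is one defensible
choice among several; it is not claimed to reproduce any particular published
component count.

**Loading robustness** uses the bootstrap ratio convention: participants are
resampled with replacement, each replicate is re-standardized and refit, the
replicate's components are aligned to the original fit (order and sign by
maximal absolute correlation between replicate X-scores and the original
scores of the same resampled rows), and per-feature loading means and
standard errors are accumulated. `Z = bootstrap mean / bootstrap SE`, and
`|Z| > 3` (roughly two-sided p ≈ 0.003) flags robust contributors. The
alternative ratio (original loading / bootstrap SE) is available via the
`ratio` argument.

**Latent-score/test correlations** are Pearson correlations of the latent
brain scores with each cognitive test, Bonferroni-corrected over the
components × tests family. A caveat documented by the test suite: computed
in-sample these correlations are optimistically biased under the null
(the scores are chosen to covary with `Y`), so their *calibration* is only
guaranteed out of sample; in-sample they are descriptive, which matches how
such tables are conventionally reported.

## 2. Site harmonization

Multi-site feature tables carry additive (location) and multiplicative
(scale) site artifacts. The harmonizer implements the standard parametric
empirical-Bayes location/scale batch adjustment: per feature, a linear model
with site indicators and protected covariates is fit; residuals are
standardized by the pooled residual variance; per-site×feature location and
scale estimates are shrunk toward normal / inverse-gamma priors whose
hyperparameters are estimated across features within site by the method of
moments; posteriors are iterated to convergence (relative tolerance 1e−4,
cap 100 iterations). Adjusted data restore the grand mean and covariate
effects (covariates are *protected* by default; `protect_covariates=False`
residualizes them instead). The implementation agrees with the Bioconductor
`sva::ComBat` reference to the EB stopping tolerance (~1e−6 observed on a
test fixture).

Defaults mirror the study design: functional-connectivity matrices are
harmonized for age, sex, and mean head motion; diffusion (FA) matrices for
age and sex; gray-matter harmonization is off by default (the pipeline flag
enables it), since structural pipelines were already prospectively
harmonized.

Properties established on synthetic data: planted location shifts (SD 1
across features) and scale ratios up to ~2 across 4 sites are removed to
within 0.1 SD per-feature site-mean difference and site-variance ratios
within [0.8, 1.25] (median across features); a planted covariate slope is
preserved within 10%; planted brain–cognition correlations change by less
than 0.05 absolute. One intrinsic limitation: when a site shift is *identical
across features*, the empirical prior correctly concentrates on the common
shift and per-feature sampling noise survives adjustment — per-feature
guarantees require heterogeneous shifts, which is what real site artifacts
look like.

Fitting and applying are separated (`fit_harmonization` /
`apply_harmonization`) so held-out sites' data can be adjusted with training
parameters; unseen site labels raise. Features with zero within-site variance
are excluded from EB estimation and passed through with a warning.

## 3. Quality control and preparation

Boundary semantics are strict and test-pinned:

| Rule | Semantics | Default |
|---|---|---|
| Motion filter | keep mean FD strictly `<` threshold | 0.7 mm (0.5 mm sensitivity) |
| Surface holes | exclude counts strictly `>` maximum | 380 |
| Tract filter | drop tracts with unusable fraction strictly `>` maximum | 3% |

Remaining missing tract cells are imputed by per-tract means. Missing
cognitive scores are imputed by the per-test observed mean (the study's low
3–5% missingness justifies nothing richer); the missingness mask is retained
for audit, and the pipeline flag `impute_before_qc` controls whether
imputation uses the full sample (default, matching an n-of-battery reading)
or the post-QC sample. WMH volume is ICV-corrected and square-root
transformed (`sqrt(wmh/icv)`) to normalize its skew. Z-scoring uses the n−1
denominator and returns the fitted means/SDs for leakage-free held-out
standardization; zero-variance columns raise by name.

## 4. Leave-one-site-out generalizability

For each site: standardize training X and Y, fit the PLS (component count by
the sequential rule or fixed), select cognitive tests significantly
associated with the training LVs (Bonferroni, within the training fold —
`fixed_test_list` reproduces the alternative of a pre-specified list), build
a composite as the first principal component of the selected standardized
tests (sign anchored to the mean of the selected tests; a single selected
test is used standardized), then standardize the held-out site with training
parameters, predict cognition through the training `B`, and correlate
predicted with observed composites. Nothing trained ever sees the held-out
site; the suite verifies this by replacing a held-out site's cognition with
noise and checking the fold's training artifacts are unchanged. Sites with
fewer than 3 participants are skipped with a warning.

## 5. Remission prediction

The endpoint is binary remission. On each of `n_iter` (default 100)
iterations, a test set of `test_n` (default 20) participants is drawn at
random, stratified by outcome (proportional allocation with
largest-remainder rounding, so both classes always appear); features are
standardized on the training split; an elastic-net logistic regression is
tuned by inner stratified 10-fold cross-validation scored by AUC over the
grid {mixing 0.1, 0.5, 0.9} × 20 log-spaced penalty strengths (C from 1e−2
to 1e2). The penalty is chosen by the **one-standard-error rule**: among
grid points whose mean inner AUC is within one standard error of the best,
the most parsimonious wins (smallest C, then largest L1 mixing). The rule
matters for stability selection: with uninformative features the inner AUC
surface is flat, a plain argmax lands on an essentially random grid point —
often a near-ridge penalty at which *every* coefficient is nonzero — and
noise features can then spuriously "survive regularization" in most
iterations; the 1-SE rule collapses a flat surface to the strongest penalty
(intercept-only), so survival frequencies under the null are near zero. The
tuned model is refit on the full training split and scored on the held-out
20. "Surviving regularization" means a nonzero coefficient at the selected
penalty; features nonzero in strictly more than 95% of
iterations form the parsimonious set, which is then evaluated by stratified
k-fold (default 8) cross-validation of an effectively unpenalized (ridge
C=1e3 for numerical stability under separation) logistic model: pooled
out-of-fold probabilities give the AUC, and assignment at probability 0.5
(Youden-optimal threshold available via `threshold_rule="youden"`) gives the
confusion matrix. Continuous MADRS change is modeled by a single-LV PLS on
the combined clinical/demographic/cognitive/brain block, with a permutation
p-value and a random held-out split correlation.

The solver is `LogisticRegressionCV` (saga, tol 1e−3, max_iter 2000); the
tolerance was chosen so that the selected penalty and nonzero set are stable
to further tightening on the data scales used here.

## 6. Synthetic cohorts and what the validation shows

The generator plants shared latent factors: factor scores `F` drive both
blocks (`Y = F·Ly' + Ey`, `X = F·Lx' + Ex`). Each cognitive test loads on
exactly one factor with loading `sqrt(signal_strength)` against unit total
variance, so the planted fraction of Y-variance carried by the factors equals
`signal_strength` *exactly*, giving closed-form calibration. Within each
modality a sparse feature subset (`loading_sparsity`, default 10%) carries
each factor at population feature–factor correlation `x_loading_strength`
(default 0.5). Site effects follow the harmonizer's own generating model
(normal locations, inverse-gamma squared scales with mean 1); age, sex, and
(for FC only) head motion enter all features with uniform known slopes.
Remission labels are Bernoulli from a logistic model on a sparse informative
feature subset; the slope is calibrated by deterministic quadrature so the
*true* linear predictor attains the requested AUC (default 0.70) at the
requested prevalence (default 0.35, roughly the remission rate such trials
report). MADRS change shares the informative direction with a planted R²
(default 0.30). Cognitive missingness is MCAR (default 4%). Demographics
match the emulated cohort's marginals (age ~ N(68, 6), ~68% female,
education ~ N(14.8, 2.5)) for realism only.

A subtlety that shaped the recovery harness: the PLS estimate of Y-variance
explained converges to `signal_strength × R²(F|X)` — the planted fraction
*scaled by how well X linearly recovers the factor*. With the default sparse,
moderate loadings, `R²(F|X) ≈ 0.6`, so recovering `signal_strength` itself
requires planting the factor densely (half the features at correlation 0.7,
giving `R²(F|X) ≈ 0.95`); the parameter-recovery tests do exactly that and
recover planted fractions of 0.05/0.10/0.15 within ±0.01 on average.

What passing tests do **not** show about real data: the generator's factors
are exactly linear and homoscedastic, site effects follow the harmonizer's
assumed family, missingness is ignorable, and features within a block are
conditionally independent given the factors — real connectomes and
morphometry have geometric covariance structure, non-Gaussian tails, and
confounded site/population differences that none of these tests probe.

## 7. Reduced-scale defaults and reproducibility

Publication-scale resampling (5000 permutations/bootstraps, 100 prediction
iterations) is the library default at the operation level; the pipeline
configuration used by the acceptance script runs 500/500/50 and the smoke
tests run smaller still — these are the package's own desk-scale choices, and
every number in the report is computed at whatever scale the configuration
requests. A single master seed spawns independent per-stage seeds
(`numpy.random.SeedSequence`), so `run-all` is byte-identical across reruns
with the same configuration and seed; the manifest records the configuration,
package version, and derived stage seeds.

## 8. Known limitations

- Sequential permutation selection of the component count is mildly liberal
  when strong signal leaks across deflation steps; it is calibrated under the
  null and for well-separated factors.
- The bootstrap aligns components greedily by score correlation; with nearly
  degenerate singular values components can swap identity, inflating SEs and
  making flags conservative rather than anticonservative.
- The elastic-net penalty grid is fixed rather than adaptive; extremely
  high-dimensional blocks (e.g., full 210-edge FC with small n) may prefer a
  wider C range.
- Harmonization assumes at least two participants per site and removes any
  site-mean-shaped signal, including true site-level composition differences.
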