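# Methods

## The model

`xtissue` builds a polygenic expression score for a case-control phenotype
in one tissue and asks whether that score, predicted into a second tissue,
tracks a continuous clinical trait there. The training pipeline, run
independently inside every bootstrap bag, is:

1. **Correlation ranking.** Rank all candidate genes by the absolute
   Pearson correlation between their (residualized) expression and the
   current outcome, and keep the top `n = floor(samples / 10)`. Round one
   uses the binary diagnosis (0/1 coding, i.e. the point-biserial
   correlation); later rounds use the pseudo-outcome below. The divisor 10
   reflects the assumption that expression effect sizes are large enough
   for accurate classifiers to be built from a small number of strong
   predictors.
2. **L1 pruning.** Fit an L1-penalized binomial regression of diagnosis on
   the ranked genes; the penalty weight is chosen by minimum mean
   out-of-fold binomial deviance over a descending grid with stratified
   5-fold cross-validation. Genes with nonzero coefficients survive. If the
   CV-optimal penalty zeroes everything, the smallest grid penalty with at
   least one surviving gene is used instead (with a warning), so a round
   rarely returns nothing.
3. **Outcome residualization.** Fit an unpenalized binomial regression of
   diagnosis on all genes selected so far and take deviance residuals —
   the signed square roots of the per-sample deviance contributions —
   as the next round's pseudo-outcome. Deviance residuals are the
   likelihood-natural choice; Pearson residuals are available through
   `PipelineConfig(residual_type="pearson")`. Fitted probabilities are
   clipped to [1e-6, 1 - 1e-6], so separation yields finite residuals.
4. **Iteration.** Steps 1-3 repeat for `m_rounds = 2` rounds. Genes
   already selected are excluded from later rounds' candidate ranking, so
   the per-round selections are disjoint and the total predictor count is
   bounded by `m * n` (below 50 on cohorts of ~250 samples or fewer).
5. **SCAD fit.** On the union of selected genes, fit a binomial regression
   penalized by the smoothly clipped absolute deviation (SCAD) penalty
   with shape `a = 3.7`, the penalty weight again chosen by cross-validated
   deviance. SCAD shrinks small coefficients like the lasso but leaves
   large coefficients unbiased, which matters when the selected predictors
   are correlated.
6. **Prediction.** The score of a new sample is the model's linear
   predictor; the ensemble score averages linear predictors across bags.

**Bagging.** Each bag draws `ceil(2/3 * cases)` and `ceil(2/3 * controls)`
from every training cohort independently (stratification within cohort
preserves both cohort composition and class balance), combines the
subsamples, and trains steps 1-5. The default is 1000 bags. Out-of-bag
samples are recorded per bag; out-of-bag ensemble scores average only the
models that did not train on a sample. Averaging linear predictors rather
than probabilities keeps the score interpretable as a mean signature load;
every downstream test used here (rank correlation, rank-sum) is invariant
to monotone transforms, so the choice does not affect inference. A
probability-averaging switch exists (`aggregation="mean_probability"`).
When a bag's selection returns no predictors — the typical situation under
permuted labels — the bag contributes an intercept-only model rather than
being dropped, keeping the ensemble and its null distribution well defined;
a constant ensemble score is scored as 0% explained variance.

## Evaluation

- **Classification accuracy** is Nagelkerke's pseudo-R² from a logistic
  regression of diagnosis on the (out-of-bag) ensemble score:
  `R²_N = [1 - exp((2/n)(l0 - l1))] / [1 - exp((2/n) l0)]`.
- **Continuous-trait association** is Spearman's rho between predicted
  scores and the trait (HbA1c in the motivating application), with
  explained variance defined as `100 * rho²`. The p-value uses the
  t-approximation, or exact enumeration of all rank permutations when
  n <= 9 with no ties.
- **Group separation** is the two-sided Wilcoxon rank-sum test, exact when
  both groups have at most 10 tie-free observations, otherwise the normal
  approximation with tie correction (no continuity correction, so identical
  groups give p = 1 exactly). The covariate-adjusted variant residualizes
  scores on the covariates by OLS first; with no covariates it reduces to
  the plain test.
- **Permutation specificity.** Diagnosis labels are shuffled within each
  cohort (preserving per-cohort case/control counts), the entire training
  pipeline is re-run, and the cross-tissue explained variance recorded.
  The empirical p is the frequency of null values at least as large as the
  observed one — no +1 correction, reported as "< 1/B" at zero
  exceedances. Permutation re-runs may use a reduced bag count
  (`permutation_bags`) for tractability.

## Gene selection and knockout importance

Candidate genes are the union of the top-K (default 200) ranked gene-set
categories, intersected with the genes measured in every dataset; ranks
come from the input GMT's line order, treating the upstream genetic
association ranking as data. `knockout_top_categories` removes genes in the
top-N categories before training, probing whether the strongest
risk-associated sets help or mask the cross-tissue prediction. Bonferroni
correction (`alpha / n_tests`) is the only multiple-testing device used.

Leave-unit-out importance re-runs the full train + predict + associate
pipeline with one category (or one co-expression module) removed, under the
*same* seed as the baseline, so the change in explained variance reflects
gene removal only; a unit sharing no genes with the working list reproduces
the baseline bit for bit. Units are flagged when their delta lies outside
`mean ± z * SD` of all deltas, with `z` the two-sided Bonferroni normal
quantile `Phi^{-1}(1 - alpha / (2 * n_units))` (n_units = 140 gives
z = 3.57, 120 gives 3.53); a fixed multiplier can be supplied instead.
With few units this band is intentionally unreachable — the largest
possible standardized deviation among n values is (n-1)^{3/2}/n — so
meaningful profiling needs a few dozen units.

## Co-expression modules

Control-subject expression (residualized) feeds an unsigned weighted
network: adjacency `|cor(i,j)|^beta`, with `beta` the smallest integer in
1..20 whose degree distribution fits a scale-free topology with R² above
0.80. The fit statistic follows the standard convention: connectivities
are cut into 10 equal-width bins, log10(bin frequency) is regressed on
log10(mean connectivity), and the R² is sign-flipped when the slope is
positive so only decaying distributions qualify. Adjacency is transformed
to topological overlap, `TOM_ij = (sum_u a_iu a_uj + a_ij) /
(min(k_i, k_j) + 1 - a_ij)`, and modules come from average-linkage
hierarchical clustering of `1 - TOM`. The tree is cut at the midpoint of
the largest gap between consecutive merge heights — a deterministic rule
that cleanly separates block structure from background and degrades to a
single cluster when no structure exists; a fixed-quantile height cut is
available as an alternative (`method="height"`). Clusters below the minimum
module size (default 10, deliberately small so that compact, highly
predictive gene sets can surface) are left unassigned (label 0); labels are
ordered by decreasing module size.

## Preprocessing

The pipeline ingests log2-scale expression matrices; array background
correction and probe summarization are assumed upstream. Within each
cohort: duplicate gene symbols are averaged (no alias resolution — symbols
are matched verbatim); quantile normalization forces every sample onto the
common distribution of row-wise sorted means, with ties given the mean of
the reference values at their tied positions (idempotent, rank-preserving,
equalizes column means); cross-dataset analysis restricts to the
lexicographically sorted common gene set, and train/target pairs are
re-quantile-normalized jointly on their overlapping genes. Principal
component outlier flagging replaces visual inspection with a deterministic
rule: a sample is flagged when its PC1 or PC2 score is more than a
threshold (default 4) robust SDs (1.4826 * MAD) from the median.

Covariate residualization regresses each gene on site, sex, age, centered
age squared and post-mortem interval by OLS (categorical covariates one-hot
with one dropped level; collinear columns dropped via pivoted QR with a
warning; `pc1` optionally adds the dataset's first expression principal
component). Age is centered before squaring purely for numerical
conditioning — the residual space is identical. Brain pH is deliberately
not a covariate. When a cohort has more controls than cases, 1:1 propensity
matching precedes residualization: a logistic model of case status on age,
sex and PMI, then greedy nearest-neighbour matching on the logit propensity
without replacement, processing cases in descending propensity order, no
caliper.

## Synthetic data

The generator emulates the statistical structure of the motivating study
rather than any real cohort's marginals:

- **Discovery cohorts**: four case-control cohorts totalling 212 subjects
  (default), each with age, sex, PMI and site covariates whose effects load
  on random 10% gene subsets, a planted signature (60 genes, 0.8 SD
  case-control shift with per-gene random direction and magnitude in
  [0.5, 1]) and i.i.d. Gaussian noise on the log2 scale — summarized array
  expression is approximately Gaussian per gene, which is what the
  pipeline consumes.
- **Gene sets**: 200 ranked categories of 8-20 genes (median ~14), with
  each signature gene hosted by a top-20-ranked category with probability
  `concentration` (default 1.0).
- **Target tissue**: 51 subjects (9 labelled diabetic). A 22-gene subset of
  the signature loads on a per-sample latent factor `v`; the HbA1c-like
  trait is `5.5 + trait_coupling * v + noise` with `trait_coupling = -0.5`
  and noise SD 0.55 percentage points, calibrated so the oracle
  (direction-weighted signature mean) correlates with the trait at
  |rho| ~ 0.6 — the scale of effect the method is meant to detect.
  Diabetic labels go to the highest-trait samples, echoing a fixed
  diagnostic threshold on glycated hemoglobin.
- **Null variants** set the case-control effect or the trait coupling to
  zero; no special code path exists for negative controls.

The gene universe defaults to 2000 genes — a down-scaled stand-in for a
transcriptome-wide panel chosen so that the full study (training, 200
permutations, knockout profiles) runs in minutes; the pipeline itself is
size-agnostic. What passing recovery tests on these data shows is that the
machinery finds planted multi-gene signal of the stated effect size and
stays calibrated under the null; it does not show robustness to platform
effects, probe-level artifacts, non-Gaussian expression marginals or
confounding structures the generator does not emulate.

## Numerical choices

Both penalized fits run on one coordinate-descent engine (numba-compiled):
IRLS working-response cycles with exact univariate updates — soft
thresholding for L1; for SCAD the exact minimizer of the local quadratic
plus penalty, found by evaluating all stationary points and region
boundaries, since the middle SCAD region makes the univariate problem
non-convex at small curvature. A cycle that increases the penalized
objective (possible only through SCAD's non-convexity) is retried with the
global Hessian bound 1/4 as curvature, which majorizes the likelihood and
restores monotone descent. Coordinates enter through a
Karush-Kuhn-Tucker screen of the true gradient; the path over the
descending penalty grid is warm-started. Fits terminate on coefficient
stability (1e-7), a flat likelihood (mean deviance per sample below 1e-3,
i.e. effective separation, where further sweeps are statistically
meaningless), an objective stall, or 10^4 sweeps (returning the best
iterate with a warning flag). Cross-validation fold fits, which only rank
penalty values, use a relaxed tolerance (1e-5); final fits use the full
tolerance. The penalty applies on the standardized-predictor scale and the
intercept is never penalized. Unpenalized fits inside outcome
residualization and Nagelkerke's R² use statsmodels' IRLS GLM.

Determinism: every source of randomness (bag subsampling, CV folds,
permutations, the generator) derives from a single configured seed via
independent seed streams, so reruns are bit-identical and knockout deltas
of gene-disjoint units are exactly zero.

## Limitations

- The iterative selection analyzes pooled cohorts after per-cohort
  residualization; no explicit cross-cohort batch model is fitted.
- The tree-cut rule is a deterministic simplification of dynamic
  hybrid cutting; on data with nested or unevenly dense modules the two
  can differ.
- The propensity-matching dialect (greedy nearest neighbour, descending
  order, no caliper) is one standard choice; optimal matching may pair
  differently on hard cases.
- Explained variance for a continuous trait is defined as 100 * rho²
  of the Spearman correlation; other definitions (OLS R² on ranks or
  levels) give slightly different numbers.
- P-value granularity of the permutation test is 1/B; reduced-bag
  permutation re-runs trade Monte-Carlo noise in each null draw for speed.
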