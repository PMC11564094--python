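# Methods

This note documents the statistical procedures, conventions and default
parameters implemented in `ehrkit`, what the synthetic-cohort generator
does and does not emulate, and the design choices made where several
defensible options existed.

## Data model

`EHRFrame` stores patient visits as rows and measured quantities as
columns.  Numeric variables hold floats; raw categorical, boolean,
datetime and text variables hold strings; the single missing marker is NaN
for every kind, which keeps missingness counting uniform across types.
Variable kinds are inferred from content (boolean token pairs {0,1},
{true,false}, {yes,no}; fully numeric; fully date-parseable; at most
`max_categories` = 100 distinct tokens → categorical; otherwise text) and
can be overridden per column.  All alignment invariants (row/column
counts, unique identifiers, layer shapes) are re-checked by a shared
validator.

On disk a frame is an h5ad-layout hierarchical store.  The value matrix is
written as float64 bit-for-bit; string-valued raw columns are carried in a
dedicated unstructured group together with explicit missing masks, so the
round-trip is exact including missing entries and category order, and the
numeric portion of the store opens in any AnnData reader.

## Encoding

One-hot encoding emits one indicator column per category
(`<var>_<category>`, numeric suffix on collision); label encoding assigns
consecutive integer codes.  Categories are ordered lexicographically so
codes are deterministic; there is no drop-first option because the
downstream consumers are embeddings, not identifiable regressions.
Missing entries propagate (a full row of NaN indicators, or a NaN code)
and the original values are retained so decoding restores the frame
exactly.

## Quality control

*Missingness metrics* count absolute and relative missing entries per
variable and per observation; the two marginal totals always reconcile.

*Winsorization* caps each tail at its quantile using the order-statistic
convention (lower cap: `np.quantile(x, lo, method="higher")`; upper cap:
`method="lower"`).  Caps are therefore actual data values and the
operation is exactly idempotent — the linear-interpolation convention is
not, because interpolated caps re-interpolate above themselves on the tied
data they create.

*Little's MCAR test.*  Rows are grouped by missingness pattern; the grand
mean and covariance are maximum-likelihood EM estimates under a
multivariate normal model (tolerance 1e-6 on the parameter change, at most
200 iterations).  The statistic
`d² = Σ_j m_j (ȳ_obs,j − μ̂_obs,j)ᵀ Σ̂_obs,j⁻¹ (ȳ_obs,j − μ̂_obs,j)` is
referred to χ² with `Σ_j p_j − p` degrees of freedom.  All patterns are
kept by default — the per-pattern term uses the grand covariance, not a
pattern-specific estimate, so small patterns are admissible; a
`min_pattern_size` argument drops (with a warning) patterns below a chosen
size and adjusts the degrees of freedom.  Fewer than two distinct patterns
is a degenerate input.  Monte-Carlo behaviour at the documented study
conditions (500 null datasets, n = 500, four equicorrelated normals at
ρ = 0.5, 20 % MCAR): rejection rate ≈ 0.04 at α = 0.05; power against the
default MAR injection at n = 1000 is ≈ 1.

*Bias detection* reports Pearson correlations on pairwise-complete
numeric pairs, standardized mean differences
`(mean₁ − mean₂) / pooled sd` (pooled with n−1 weights; antisymmetric
under group swap), categorical value-count differences both raw and as
proportions (the field has no single normalization convention), and an
optional random-forest importance ranking for a named target.

*Sampling.*  `subsample` draws without replacement; `balanced_sample`
equalizes group sizes at the minority (undersampling, without
replacement) or majority (oversampling, with replacement) size.

## Imputation

No imputer ever alters an originally observed entry.  `impute_simple`
fills the per-variable mean/median/mode.  `impute_knn` (default k = 20)
uses Euclidean distance over jointly observed coordinates rescaled by
√(p/p_observed) — the nan-Euclidean convention — and averages the
neighbors' observed values.  `impute_missforest` initializes with
mean/mode, then revisits variables in order of increasing missingness,
regressing each on all others with a random forest fit on its observed
rows; iteration stops when the normalized sum of squared changes between
successive rounds first increases (the original MissForest rule) or after
`max_iter` rounds; label-encoded categoricals use classification forests.
All stochastic imputers take an explicit seed and are exactly
reproducible.

Expected distortions, asserted on synthetic data: under MCAR at rate r,
mean imputation preserves the mean but shrinks the standard deviation by
≈ √(1−r); under MAR with a positive driver slope it additionally biases
the mean toward the observed stratum, and the iterative-forest imputer
reduces both the location and the scale distortion.

## Normalization

All transforms fit on non-missing entries and leave missing entries
missing; fitted parameters are returned in a record sufficient to
reproduce the transform.  Conventions: `log` is log1p (an optional
pre-offset covers strictly positive data); `scale` uses the population
(1/n) standard deviation; constant columns scale to all-zeros with a
warning; `power` is the Yeo–Johnson family with maximum-likelihood λ
followed by standardization; `quantile` maps each variable onto the mean
order-statistic profile across the targeted variables, with averaged-tie
ranks.  With a `group_key` every transform is fit and applied per group;
a single group reproduces the joint transform exactly.  Group-wise
scaling removes between-group location/scale differences — useful when
the differences are nuisance, hazardous when they are signal, which is
precisely the normalization-bias pattern the bias screens are meant to
catch.  `regress_out` replaces variables by OLS residuals (intercept
included; pseudo-inverse with a warning when covariates are
rank-deficient).

## Patient landscape

Highly variable features are ranked by the variance of non-missing values
(a mean-scaled dispersion is unsuitable for signed clinical variables).
PCA centers but does not rescale — normalization is an explicit prior
step — and stores scores, loadings and explained-variance ratios.  The
neighbor graph stores exact k-nearest distances (no self-edges) and
union-symmetrized connectivities; default k = 15.  UMAP runs on the same
representation with the graph's k and is deterministic for a fixed seed.
Leiden clustering maximizes the RB-configuration quality function on the
connectivity graph; labels are contiguous from 0 and deterministic for a
fixed seed.  A resolution → 0 limit merges everything into one cluster
only on a connected graph; disconnected components never merge.

## Feature ranking and survival statistics

Each group is tested against the union of the other groups.  Numeric
variables use Welch's unequal-variance t-test — the safer default for
heterogeneous clinical groups; categorical variables use the
likelihood-ratio g-test `G = 2 Σ O ln(O/E)` on the group-vs-rest ×
category table (expected counts from margins; observed zeros contribute
nothing; zero-expectation categories are dropped).  Benjamini–Hochberg
adjustment is applied across features within each group.  The step-up map
is monotone and order-preserving; it is *not* idempotent as a function of
p-vectors (e.g. [0.04, 0.5] → [0.08, 0.5] → [0.16, 0.5]), so only
monotonicity is asserted.

Survival estimation is delegated to lifelines: Kaplan–Meier product-limit
curves with the exponential-Greenwood (log(−log)) 95 % band, which keeps
bounds inside [0, 1]; the multivariate log-rank test with the standard
hypergeometric tie handling, χ²(k−1); Cox proportional hazards by partial
likelihood, reporting log hazard ratios with standard errors, 95 % CIs
and per-observation partial hazards.  The concordance index counts
comparable pairs in which the higher-hazard subject fails earlier; its
95 % CI is the 2.5/97.5 percentile interval over 1000 bootstrap resamples
of the (hazard, duration, event) triples.  GLMs come from statsmodels
(gaussian/binomial/poisson/gamma/inverse-gaussian); nested models are
compared by likelihood ratio with dof = parameter-count difference (dof
0 → p = 1).

## Causal inference

The causal graph is a user-supplied DAG.  d-separation is decided by
moralized-ancestral-graph reachability (implemented here, cross-checked in
tests against an independent graph library).  The adjustment set is the
minimal-cardinality backdoor set — no treatment descendants, blocks all
backdoor paths in the graph with the treatment's outgoing edges removed —
searched in order of increasing size with lexicographic tie-breaking.  The
effect is the treatment coefficient of OLS(outcome ~ treatment +
adjustment set), in outcome units per unit treatment.

Refuters: placebo treatment, dummy outcome and random common cause
average over 20 independent simulations (a single permutation's sampling
noise would be comparable to the pass threshold at moderate n); the pass
tolerance for "near zero"/"near reference" is max(0.1·|reference|, 0.05)
and is configurable.  The data-subset refuter re-estimates on ten random
80 % subsets; the bootstrap refuter checks that the reference lies inside
the 95 % percentile interval of 200 resampled estimates; the
unobserved-common-cause refuter reports a sensitivity curve over a grid of
simulated confounder strengths rather than a pass/fail — no threshold
there is principled.  All refuters are deterministic given the seed.

## Cohort tracking

The tracker logs monotone filtering only (a grown cohort is rejected).
Each step stores counts before/after, the free-text reason, and
distribution snapshots of the tracked columns — category counts, or
mean/sd/quartiles for numeric columns — never row identifiers, keeping
logs small and free of direct identifiers.  Step k's "before" always
equals step k−1's "after", and the flow export's excluded counts sum to
the total attrition.  Logs serialize to JSON.

## Synthetic cohorts

The generator produces what the analysis stages need to be verified:
equicorrelated Gaussian features (shared-factor construction) with
optional per-group mean shifts, categoricals with fixed level
probabilities, exponential survival times per group hazard with
independent exponential censoring, and linear-Gaussian structural causal
models sampled ancestrally with the true total effect (sum over directed
paths of coefficient products) recorded for harnesses.

Missingness injectors: MCAR removes entries independently at a fixed
rate; MAR standardizes a complete driver column (population convention)
and removes the target entry with probability
`logistic(scale·z + offset)`, defaults scale = 1.2 and offset = −0.6 — a
strong observable dependence with an overall rate near one third; MNAR
applies the same map to the value being removed itself.  The Bernoulli
draw uses the probabilities directly (no thresholding step).  The
logistic is 1/(1+e^(−x)).

What the generator does *not* emulate: longitudinal vital-sign waveforms,
free-text notes, informative censoring, non-Gaussian marginals and
non-linear structural equations.  Tests passing on these cohorts
demonstrate correctness of the estimators under their stated assumptions,
not robustness to real-world violations of those assumptions.

## Verification problem sizes

The acceptance script and test suite use: 500 null datasets of n = 500
with four ρ = 0.5 normals at 20 % MCAR for Little's-test calibration and
n = 1000 for MAR power; n = 100 000 for the √0.7 variance-shrinkage ratio
at 30 % MCAR; 20 replicates of n = 1000 with 30-tree forests for the MAR
imputation comparison; all 63 event/censor patterns at n = 6 for the
Kaplan–Meier oracle, 500 null replicates for log-rank uniformity and
n = 2000 for Cox recovery of ln 2; n = 5000 with one confounder and a
binarized treatment for causal recovery of a true effect of 2.0.  These
sizes give Monte-Carlo error comfortably inside the asserted tolerances
while keeping a full run around a minute on one CPU.

## Known limitations

Little's test assumes multivariate normality and tests only mean
differences across patterns; it has no power against MCAR-mean-preserving
MNAR mechanisms.  The MissForest stopping rule can terminate one round
past the optimum (the last decrease is kept).  The backdoor search is
exponential in the number of candidate covariates and intended for
expert-curated graphs of modest size.  The quantile-normalization
reference profile is computed from the targeted variables themselves, so
adding a variable changes the reference.  Datetime and text variables are
carried and round-tripped but not analyzed.
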