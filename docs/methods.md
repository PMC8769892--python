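# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they hold, what the synthetic benchmark does and does not
emulate, and the numerical and design choices made where the procedure was
genuinely open.

## Per-pair model

The unit of analysis is one gene pair's 2-D scatter over samples. The
working model is a finite mixture of bivariate Gaussians: each component is
one "mode" of co-expression, typically induced by an experimental
condition. Correlation is only meaningful within a component, so every
downstream statistic (similarity, power, context association) is computed
per component, never on the pooled scatter.

Samples leave a pair's analysis for exactly one reason each, encoded in a
per-pair state string: `9` missing in either gene, `6` pre-clustering
Tukey outlier, `7` removed at or after clustering, `0`–`5` retained
cluster index. The `7` code deliberately covers three situations —
within-cluster Tukey outliers, members of components smaller than the
minimum cluster size, and members of components that failed the
minimum-correlation screen — because the serialized alphabet reserves
single digits for retained clusters only. Pre-clustering outliers are
detected on each gene's marginal values of the pairwise-complete set
independently, and the flags are unioned; a joint 2-D outlier rule would
be a reasonable alternative but the marginal rule matches how the fences
are defined.

## Mixture fitting and selection

EM on full-covariance bivariate Gaussians, k = 1..5 by default, selected
by BIC (parameter count 6k − 1). Initialisation is k-means++ seeding plus
at most 10 Lloyd iterations; EM convergence is declared when the mean
per-sample log-likelihood changes by less than 1e-5 (at most 300
iterations; non-convergent k are skipped). The 1e-5 tolerance was chosen
because K selection is driven by BIC differences orders of magnitude
larger than the residual likelihood drift, while a 1e-6 tolerance roughly
doubles EM iterations on unstructured pairs and with it the cost of the
all-pairs pass. Covariances carry a 1e-6 ridge. The EM is a dedicated
numba-compiled implementation: the all-pairs pass fits ~10⁵ mixtures for a
200-gene matrix and a compiled kernel keeps that at minutes; tests
cross-check K selection and labels against scikit-learn's mixture on
separable instances, and the BIC argmin against an independently
recomputed likelihood.

Clusters below the minimum size (default 30 samples, user-settable) are
dropped; survivors are renumbered by decreasing size with ties broken by
lower mean x. Determinism: every pair derives its seed from the global
seed and the gene indices, so results are independent of evaluation order
and identical across runs.

Known limitation: mixtures can merge distinct modes that line up
diagonally (grid-corner geometry between two pairs split by *different*
factors), producing occasional spurious moderate correlations; such
merges are the main source of unplanted categorical edges in the
synthetic benchmark (a handful out of thousands of pairs).

## Power filter

A cluster of n samples supports correlation magnitude r only if
n ≥ ⌈((z₁₋α/₂ + z_power)/atanh r)² + 3⌉ — the standard Fisher-z sample
size for a two-sided test of ρ = 0 with the +3 small-sample correction.
Two-sidedness is required to reproduce the canonical worked value
(r = 0.85, α = 0.001, power = 0.8 → n = 14). The asymptotic formula is
mildly conservative at small n: the exact test's simulated power at the
returned n runs ~3–4 points above the asymptotic value (e.g. 0.85 vs 0.81
at n = 14), which the acceptance checks account for.

## Context association

*Comparison population.* Proportion tests compare the cluster against all
GEM samples by default; samples unusable for the pair (missing in either
gene) count as outside the cluster. This is what allows a cluster of
samples in which a condition-restricted gene is detectable at all to be
associated with that condition — under a complete-samples-only population
the label's prevalence in such a comparison is 1 and the test is
degenerate, so condition-restricted co-expression could never be
annotated and the missingness screen would have nothing to protect.
`ContextThresholds(comparison="complete")` selects the stricter variant.

*Categorical.* One-proportion z-tests (normal approximation, no
continuity correction), enrichment one-sided greater inside the cluster
and depletion one-sided less outside, both at α = 0.001, with the null
proportion fixed at the label's prevalence. Degenerate prevalence or an
empty side is untestable, never retained.

*Quantitative.* Per-gene OLS of in-cluster expression on the covariate;
both genes must reach R² > 0.3 and slope p < 0.001. The regression
direction (expression on covariate, per gene, both-genes rule) is an
interpretation choice — it treats the two genes symmetrically, consistent
with the confounding screen's both-genes rule.

*No multiplicity correction* is applied across variables and labels; the
α = 0.001 thresholds are fixed by design. Calibration of each individual
test is verified by simulation instead.

## Bias screens

*Missingness.* Student's t-test on the two genes' missingness indicator
vectors over all samples. Default retention keeps the association when
the patterns are **not** significantly different (p ≥ 0.001), matching
the screen's purpose of requiring similar detection patterns; the
opposite reading ("retain when significant") exists in the wild and is
available as `miss_retain="different"`, but flipping it silently would
invert the spoke protection, so it is an explicit switch.

*Confounding.* Welch's test (one-way Welch ANOVA reduces to Welch's t for
two groups) per gene, in-cluster vs out-of-cluster, both genes must reject
at α = 0.001. The out group defaults to the comparison samples outside the
cluster excluding pre-clustering outliers — those are extreme by
construction and would make a small out group trivially "different"; a
category-complement out group is available. Two guard rails:

* the out group must contain at least max(10, 5% of the comparison set)
  samples — a cluster spanning essentially all usable samples has no
  context to demonstrate;
* a gene detected in at most 10% of an out group of ≥ 10 samples is
  treated as detection-restricted and passes with p = 0: presence versus
  absence of detection is maximal differential expression, and the
  missingness screen remains the arbiter of whether the *pair's* patterns
  match. The 10% threshold keeps a handful of incidentally missing values
  from triggering the rule.

## Edge ranking

rank_score = |r| · min(−log₁₀ p_ctx, 20)/20 · q, with p_ctx the weakest
context p-value of the record and q the mean per-gene R² for quantitative
contexts (1 for categorical). The ingredients — similarity, context
p-values, R² — are the standard ones; this particular combination is a
stand-in of this package's own design, monotone in each ingredient,
capped at p = 0, with a deterministic lexicographic tie-break. No global
correlation threshold is applied to the finished network: a pair may
legitimately carry several context edges, so single-threshold methods
(including random-matrix thresholding) do not apply.

## Assumption audit

Royston's (1992) H-test combines per-margin Shapiro–Wilk statistics via
his normalising transforms (separate polynomial forms for 4 ≤ n ≤ 11 and
12 ≤ n ≤ 2000, hence the n range) with equivalent degrees of freedom
e = 2/(1 + c*), where c* is the published function of the margins'
correlation with λ = 5, u = 0.715. The correlation enters as a magnitude:
dependence is symmetric in the correlation's sign, and this keeps the
test invariant under sign-flipping affine maps (the raw-signed variant
found in some implementations is not). e is clamped to [1, 2].

Breusch–Pagan is used in the studentised LM form — n·R² of the squared
OLS residuals regressed on the single predictor, against χ²(1) — which is
the appropriate single-regressor form for a pairwise scatter; a perfect
fit returns p = 1.

Multimodality is flagged when the pairwise mixture engine selects K ≥ 2.

## Synthetic benchmark

The default scenario emulates a controlled multi-factor design: 2
subspecies × 5 treatments × 30 time points (0–8 h) = 300 samples, 210
genes, expression on a log-like scale around a base level of 5 with
noise sd 0.5 and 1% uniform missingness. Archetypes (20 pairs each unless
noted):

* **bimodal-split** — subspecies-specific modes ≥ 4 sd apart; shared
  latent factor gives ρ = 0.8 inside one subspecies, independence in the
  other. Expected: one `Subspecies` edge per pair.
* **category-specific** — co-expression (ρ ≈ 0.9) plus a +2 shift inside
  the heat *and* heat-recovery treatments. The co-expressed mode spans
  two of five treatments (40% of samples) deliberately: a 20% minority
  mode shifted far enough to be separable pokes beyond the pairwise Tukey
  fences and is clipped before it can be clustered, which is itself an
  instructive failure of fence-based outlier removal on mixtures.
  Expected: edges labelled heat and/or heat-recovery (either matches the
  planted truth).
* **spoke flavour** (5 pairs, recorded as category-specific) — both genes
  undetected outside control, co-expressed within it via a latent factor.
  Expected: a `Treatment=control` edge; with `spoke_time_driven=True`
  the within-control driver is the time covariate, which additionally
  creates spoke-hazard correlations with every basal gene — those must be
  removed by the missingness screen, and the test suite runs that variant.
* **confounded** — gene A is a pure function of time; gene B follows time
  everywhere plus a heat-specific offset (+2.0, slightly time-dependent).
  The heat cluster is genuinely correlated but only through shared time.
  Expected: zero category edges (gene A fails the Welch screen); the
  genuinely time-co-expressed background cluster may yield `Time` edges.
  B's basal time trend departs from the textbook "flat outside the
  category" picture so that its heat mode stays inside the pair's Tukey
  fences at this sample size.
* **basal-pair** — both genes track time everywhere (clock-like).
  A whole-matrix cluster has no out group and is dropped; when the BIC
  splits the time line into segments, segment edges labelled `Time` are
  genuine and allowed.
* **null** — independent noise. Expected: essentially no edges (≤ 1% of
  pairs).

Because all basal, confounded-A and time-driven spoke genes share the one
time covariate, *cross-pair* edges among them are genuine co-expression
and do appear; recovery is therefore scored per planted pair and
archetype, with unplanted edges tallied separately. What passing recovery
shows about real data is limited: the generator has Gaussian noise, a
single quantitative covariate, no batch effects, no count-model
(negative-binomial) behaviour, and planted modes that are separable by
construction; it validates the pipeline's logic, not its sensitivity on
noisy compendia.

## Problem sizes and runtime

The default scenario's all-pairs pass covers ~22k pairs × up to 5 EM fits
and runs in roughly five minutes on one core; the calibration and
Monte-Carlo checks use 1000–50,000 replicates each. These sizes were
chosen as the smallest at which the planted-recovery and calibration
bands are statistically meaningful.

## Degenerate inputs and tie-breaks

Fewer than 4 finite values: no outlier flags (warned). Zero-variance
cluster margins: correlation undefined, cluster excluded. Zero-variance
Welch groups: variance floor 1e-12 (warned). Identical missingness
vectors with no variance: p = 1 (p = 0 if disjoint and constant). BIC
ties prefer smaller k; cluster renumbering ties prefer lower mean x;
ranking ties break lexicographically. Network and cluster files write
floats in shortest round-trip form, so write→read is exact and reruns are
byte-identical.
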