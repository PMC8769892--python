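"""Context association and bias correction for surviving clusters.

Each power-filtered cluster is tested for association with every
experimental variable. Categorical variables use two one-proportion z-tests:
the target label must be enriched inside the cluster and depleted outside it
(both one-sided, normal approximation, no continuity correction).
Quantitative variables use per-gene ordinary least squares of the in-cluster
expression on the covariate; both genes must clear the R² and slope-p
thresholds.

Two bias screens then guard the retained associations:

* a two-sample Student t-test on the genes' missingness indicator vectors —
  a cluster produced by one gene being undetected outside a condition while
  its partner is ubiquitously expressed would otherwise create an
  artifactual "spoke" of edges around the restricted gene;
* a Welch test per gene comparing in-cluster versus out-of-cluster
  expression — a context label is only kept when *both* genes are
  differentially expressed for it, which removes associations driven by a
  covariate (e.g. time) confounded with the category in just one gene.

By default the comparison population for the proportion tests is all GEM
samples: samples unusable for the pair (missing in either gene) count as
outside the cluster, which is what lets a cluster of samples where a
condition-restricted gene is detectable be associated with that condition
in the first place. A complete-samples-only variant is available via
``ContextThresholds(comparison="complete")``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from scipy import stats

from .edge_ranking import EdgeRecord
from .gem_io import GEM, AnnotationTable
from .pairwise_engine import PairClusterResult

logger = logging.getLogger(__name__)

_DIGITS = tuple("012345")

__all__ = [
    "ContextThresholds",
    "ContextResult",
    "BiasTestResult",
    "categorical_association",
    "quantitative_association",
    "missingness_similarity",
    "confound_variance_test",
    "annotate_clusters",
]


@dataclass(frozen=True)
class ContextThresholds:
    """All Step 6-8 thresholds and behavioural switches.

    ``miss_retain="similar"`` keeps a cluster when the missingness patterns
    are *not* significantly different (p >= miss_alpha), matching the stated
    purpose of the screen; ``"different"`` implements the opposite reading
    (retain when p < alpha). ``outgroup`` selects the Welch-test out group:
    all non-cluster samples, or the complement of the tested category.
    """

    assoc_alpha: float = 0.001
    min_r2: float = 0.3
    miss_alpha: float = 0.001
    confound_alpha: float = 0.001
    outgroup: str = "noncluster"          # or "category-complement"
    comparison: str = "all"               # or "complete"
    miss_retain: str = "similar"          # or "different"

    def __post_init__(self) -> None:
        if self.outgroup not in ("noncluster", "category-complement"):
            raise ValueError(f"unknown outgroup {self.outgroup!r}")
        if self.comparison not in ("all", "complete"):
            raise ValueError(f"unknown comparison set {self.comparison!r}")
        if self.miss_retain not in ("similar", "different"):
            raise ValueError(f"unknown miss_retain {self.miss_retain!r}")


@dataclass
class ContextResult:
    """Outcome of one cluster x variable(/label) association test."""

    variable: str
    kind: str                       # "categorical" | "quantitative"
    label: str | None = None
    p_in: float | None = None
    p_out: float | None = None
    r2_i: float | None = None
    r2_j: float | None = None
    p_slope_i: float | None = None
    p_slope_j: float | None = None
    retained: bool = False
    untestable: bool = False


@dataclass
class BiasTestResult:
    """Step 7/8 p-values attached to one retained association."""

    missingness_p: float
    confound_p_i: float | None = None
    confound_p_j: float | None = None


def categorical_association(in_mask, labels, label: str,
                            alpha: float = 0.001) -> ContextResult:
    """Two one-proportion z-tests of a label against a cluster.

    ``labels`` covers the comparison population; ``in_mask`` marks cluster
    membership within it. Test 1: the label's frequency inside the cluster
    exceeds its overall prevalence (one-sided greater). Test 2: its
    frequency outside the cluster falls below the prevalence (one-sided
    less). Retained only when both p-values are below ``alpha``. Degenerate
    prevalence (0 or 1) or an empty in/out group is untestable.
    """
    in_mask = np.asarray(in_mask, bool)
    labels = np.asarray(labels, object)
    hits = labels == label
    res = ContextResult(variable="", kind="categorical", label=label)
    n_in = int(in_mask.sum())
    n_out = int((~in_mask).sum())
    p0 = float(hits.mean()) if len(hits) else 0.0
    if n_in < 2 or n_out < 1 or p0 <= 0.0 or p0 >= 1.0:
        res.untestable = True
        return res
    se_in = np.sqrt(p0 * (1.0 - p0) / n_in)
    se_out = np.sqrt(p0 * (1.0 - p0) / n_out)
    z_in = (hits[in_mask].mean() - p0) / se_in
    z_out = (hits[~in_mask].mean() - p0) / se_out
    res.p_in = float(stats.norm.sf(z_in))
    res.p_out = float(stats.norm.cdf(z_out))
    res.retained = res.p_in < alpha and res.p_out < alpha
    return res


def quantitative_association(in_mask, values, x, y, alpha: float = 0.001,
                             min_r2: float = 0.3) -> ContextResult:
    """Per-gene OLS of in-cluster expression on a quantitative covariate.

    The cluster is annotated with the variable only when *both* genes reach
    R² > ``min_r2`` with slope p < ``alpha``. Fewer than 5 in-cluster samples
    with a finite covariate, or a constant covariate, is untestable.
    """
    in_mask = np.asarray(in_mask, bool)
    values = np.asarray(values, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    res = ContextResult(variable="", kind="quantitative")
    usable = in_mask & np.isfinite(values) & np.isfinite(x) & np.isfinite(y)
    if usable.sum() < 5 or np.ptp(values[usable]) == 0.0:
        res.untestable = True
        return res
    t = values[usable]
    for attr_r2, attr_p, expr in (("r2_i", "p_slope_i", x[usable]),
                                  ("r2_j", "p_slope_j", y[usable])):
        if np.ptp(expr) == 0.0:
            setattr(res, attr_r2, 0.0)
            setattr(res, attr_p, 1.0)
            continue
        fit = stats.linregress(t, expr)
        setattr(res, attr_r2, float(fit.rvalue ** 2))
        setattr(res, attr_p, float(fit.pvalue))
    res.retained = (res.r2_i > min_r2 and res.r2_j > min_r2
                    and res.p_slope_i < alpha and res.p_slope_j < alpha)
    return res


def missingness_similarity(miss_i, miss_j, alpha: float = 0.001) -> float:
    """Student's t-test p-value comparing two genes' missingness indicators.

    Identical patterns (including two fully observed genes) give p = 1;
    completely disjoint constant patterns give p = 0.
    """
    a = np.asarray(miss_i, bool).astype(float)
    b = np.asarray(miss_j, bool).astype(float)
    if a.shape != b.shape:
        raise ValueError("missingness vectors must have equal length")
    if a.std() == 0.0 and b.std() == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def confound_variance_test(expr, in_mask, out_mask, alpha: float = 0.001) -> float:
    """Welch test p-value of one gene's expression, in-group vs out-group.

    For two groups Welch's one-way ANOVA reduces to Welch's t-test. A group
    with zero variance is handled with a variance floor of 1e-12 (logged).
    Fewer than 3 usable samples in either group is a precondition error.
    """
    expr = np.asarray(expr, float)
    in_mask = np.asarray(in_mask, bool)
    out_mask = np.asarray(out_mask, bool)
    g1 = expr[in_mask & np.isfinite(expr)]
    g2 = expr[out_mask & np.isfinite(expr)]
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError(
            f"confound test needs >=3 samples per group, got {len(g1)}/{len(g2)}"
        )
    v1 = g1.var(ddof=1)
    v2 = g2.var(ddof=1)
    if v1 < 1e-12 or v2 < 1e-12:
        logger.warning("zero-variance group in Welch test; variance floor applied")
        v1 = max(v1, 1e-12)
        v2 = max(v2, 1e-12)
        se2 = v1 / len(g1) + v2 / len(g2)
        t = (g1.mean() - g2.mean()) / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / len(g1)) ** 2 / (len(g1) - 1)
                         + (v2 / len(g2)) ** 2 / (len(g2) - 1))
        return float(2.0 * stats.t.sf(abs(t), df))
    return float(stats.ttest_ind(g1, g2, equal_var=False).pvalue)


def _confound_or_restricted(expr, in_mask, out_mask) -> float:
    """Welch screen with a special case for detection-restricted genes.

    A gene with expression detected in the cluster but (essentially) never
    in a substantial out group cannot be Welch-tested, yet its in/out
    difference is maximal — presence versus absence of detection. Such genes
    pass the screen with p = 0. "Essentially never" means detected in at
    most 10% of an out group of at least 10 samples, so a handful of
    incidentally missing values is never read as restricted expression;
    a gene unusable inside the cluster is a precondition error.
    """
    expr = np.asarray(expr, float)
    out_mask = np.asarray(out_mask, bool)
    finite = np.isfinite(expr)
    n_in = int((np.asarray(in_mask, bool) & finite).sum())
    n_out_total = int(out_mask.sum())
    n_out = int((out_mask & finite).sum())
    restricted = n_out <= max(2, int(0.1 * n_out_total))
    if n_in >= 3 and n_out_total >= 10 and restricted:
        return 0.0
    return confound_variance_test(expr, in_mask, out_mask)


def _comparison_mask(states: np.ndarray, comparison: str) -> np.ndarray:
    if comparison == "all":
        return np.ones(states.shape, bool)
    return np.isin(states, _DIGITS) | (states == "7")


def annotate_clusters(clusters: Iterable[PairClusterResult], gem: GEM,
                      annotations: AnnotationTable,
                      thresholds: ContextThresholds = ContextThresholds(),
                      stats_out: dict | None = None) -> Iterator[EdgeRecord]:
    """Associate clusters with contexts and screen out biased associations.

    Yields one edge per (cluster, retained context); clusters with no
    retained context produce nothing.
    """
    counts = {"clusters_in": 0, "assoc_candidates": 0,
              "failed_missingness": 0, "failed_confound": 0, "edges_out": 0}
    for res in clusters:
        st = np.array(list(res.states), dtype=object)
        x_all = gem.row(res.gene_i)
        y_all = gem.row(res.gene_j)
        miss_p = missingness_similarity(gem.missing_mask(res.gene_i),
                                        gem.missing_mask(res.gene_j))
        if thresholds.miss_retain == "similar":
            miss_ok = miss_p >= thresholds.miss_alpha
        else:
            miss_ok = miss_p < thresholds.miss_alpha
        comp = _comparison_mask(st, thresholds.comparison)
        # pre-clustering outliers are extreme by construction and would bias
        # a small Welch out group; they are excluded from out groups. Members
        # of discarded clusters ('7') stay: they are ordinary samples whose
        # cluster simply was not retained.
        pre_outlier = st == "6"
        min_out = max(10, int(np.ceil(0.05 * comp.sum())))
        for cs in res.clusters:
            counts["clusters_in"] += 1
            in_all = st == str(cs.index)
            in_comp = in_all[comp]
            retained: list[ContextResult] = []
            for var, labs in annotations.categorical.items():
                for label in sorted(set(labs[comp])):
                    cr = categorical_association(
                        in_comp, labs[comp], label, thresholds.assoc_alpha
                    )
                    cr.variable = var
                    if cr.retained:
                        retained.append(cr)
            for var, vals in annotations.quantitative.items():
                cr = quantitative_association(
                    in_all, vals, x_all, y_all,
                    thresholds.assoc_alpha, thresholds.min_r2,
                )
                cr.variable = var
                if cr.retained:
                    retained.append(cr)
            counts["assoc_candidates"] += len(retained)
            if not retained:
                continue
            if not miss_ok:
                counts["failed_missingness"] += len(retained)
                continue
            for cr in retained:
                if (thresholds.outgroup == "category-complement"
                        and cr.kind == "categorical"):
                    out_all = (annotations.categorical[cr.variable] != cr.label) \
                        & ~in_all & ~pre_outlier
                else:
                    out_all = comp & ~in_all & ~pre_outlier
                if out_all.sum() < min_out:
                    # cluster spans (nearly) the whole comparison set: no
                    # meaningful out group, context specificity cannot be
                    # demonstrated
                    counts["failed_confound"] += 1
                    continue
                try:
                    p_i = _confound_or_restricted(x_all, in_all, out_all)
                    p_j = _confound_or_restricted(y_all, in_all, out_all)
                except ValueError:
                    counts["failed_confound"] += 1
                    continue
                if not (p_i < thresholds.confound_alpha
                        and p_j < thresholds.confound_alpha):
                    counts["failed_confound"] += 1
                    continue
                counts["edges_out"] += 1
                yield EdgeRecord(
                    gene_i=res.gene_i, gene_j=res.gene_j,
                    cluster_index=cs.index, num_clusters=res.k,
                    cluster_size=cs.size, method=cs.method, r=cs.r,
                    variable=cr.variable, kind=cr.kind, label=cr.label,
                    p_in=cr.p_in, p_out=cr.p_out,
                    r2_i=cr.r2_i, r2_j=cr.r2_j,
                    p_slope_i=cr.p_slope_i, p_slope_j=cr.p_slope_j,
                    missingness_p=miss_p,
                    confound_p_i=p_i, confound_p_j=p_j,
                    states=res.states,
                )
    if stats_out is not None:
        stats_out.update(counts)
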