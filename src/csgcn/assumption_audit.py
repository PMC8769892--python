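"""Diagnostics for the distributional assumptions behind network edges.

Traditional co-expression networks score every pair with a single
correlation, implicitly assuming the pair's scatter is well-behaved:
bivariate normal (for Pearson-type scores) and homoscedastic. This module
audits a set of edges for those assumptions and for multimodality:

* Royston's (1992) multivariate extension of the Shapiro-Wilk test —
  per-margin W statistics are transformed to approximately standard-normal
  z-values, converted to chi-square-like contributions and combined with
  equivalent degrees of freedom that shrink as the margins become more
  correlated;
* the Breusch-Pagan Lagrange-multiplier test in its studentised (n·R² of
  squared residuals on the predictor) single-regressor form;
* the pairwise Gaussian-mixture fit of the clustering engine — a
  BIC-selected K >= 2 flags the scatter as multimodal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

from .gem_io import GEM
from .pairwise_engine import fit_pair_clusters, tukey_mask

logger = logging.getLogger(__name__)

__all__ = ["AuditReport", "royston_normality", "breusch_pagan", "audit_edges"]


def _shapiro_z(values: np.ndarray) -> float:
    """Royston's normalising transform of the Shapiro-Wilk W statistic."""
    n = len(values)
    w = stats.shapiro(values).statistic
    if n <= 11:
        g = -2.273 + 0.459 * n
        m = 0.5440 - 0.39978 * n + 0.025054 * n ** 2 - 0.0006714 * n ** 3
        s = math.exp(1.3822 - 0.77857 * n + 0.062767 * n ** 2 - 0.0020322 * n ** 3)
        return (-math.log(g - math.log(1.0 - w)) - m) / s
    x = math.log(n)
    m = -1.5861 - 0.31082 * x - 0.083751 * x ** 2 + 0.0038915 * x ** 3
    s = math.exp(-0.4803 - 0.082676 * x + 0.0030302 * x ** 2)
    return (math.log(1.0 - w) - m) / s


def royston_normality(x, y) -> float:
    """Royston's H-test p-value for bivariate normality of (x, y).

    Valid for 4 <= n <= 2000. The margins' z-transformed Shapiro-Wilk
    statistics are combined with equivalent degrees of freedom
    e = 2 / (1 + c*) where c* is a function of the margins' correlation
    magnitude (the dependence adjustment is symmetric in the correlation's
    sign, which keeps the test invariant under sign-flipping affine maps).
    A constant margin returns p = 0 (degenerate, logged).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 4 or n > 2000:
        raise ValueError(f"Royston test requires 4 <= n <= 2000, got {n}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        logger.warning("constant margin in Royston test; returning p = 0")
        return 0.0
    z1 = _shapiro_z(x)
    z2 = _shapiro_z(y)
    u = 0.715
    lam = 5.0
    ln = math.log(n)
    v = 0.21364 + 0.015124 * ln ** 2 - 0.0018034 * ln ** 3
    c = abs(float(stats.pearsonr(x, y).statistic))
    nc = (c ** lam) * (1.0 - (u * (1.0 - c) ** u) / v)
    e = 2.0 / (1.0 + nc)
    e = min(max(e, 1.0), 2.0)
    g1 = stats.norm.ppf(stats.norm.cdf(-z1) / 2.0) ** 2
    g2 = stats.norm.ppf(stats.norm.cdf(-z2) / 2.0) ** 2
    h = e * (g1 + g2) / 2.0
    return float(stats.chi2.sf(h, e))


def breusch_pagan(x, y) -> float:
    """Breusch-Pagan heteroscedasticity p-value for the regression y ~ x.

    Studentised LM form: n times the R² of the auxiliary regression of the
    squared OLS residuals on x, against chi-square with 1 df. Requires
    n >= 5 and non-constant x; a perfect fit (zero residuals) gives p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 5:
        raise ValueError(f"Breusch-Pagan test requires n >= 5, got {len(x)}")
    if np.ptp(x) == 0.0:
        raise ValueError("predictor is constant")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    if np.max(resid ** 2) < 1e-24:
        return 1.0
    exog = np.column_stack([np.ones_like(x), x])
    _, lm_pvalue, _, _ = het_breuschpagan(resid, exog)
    return float(lm_pvalue)


@dataclass
class AuditReport:
    """Aggregate assumption-audit outcome over a set of edges."""

    n_edges_tested: int
    n_skipped: int
    fraction_failing_normality: float
    fraction_failing_equal_variance: float
    fraction_failing_either: float
    fraction_multimodal_among_nonnormal: float
    per_edge: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return self.per_edge


def _edge_genes(edge) -> tuple[str, str]:
    if hasattr(edge, "gene_i"):
        return edge.gene_i, edge.gene_j
    gi, gj = edge
    return gi, gj


def audit_edges(gem: GEM, edges, alpha: float = 0.01,
                outlier_removal: bool = True, max_k: int = 5,
                min_cluster_size: int = 30, seed: int = 0) -> AuditReport:
    """Audit each edge's pairwise scatter on pairwise-complete samples.

    Each edge (any object with ``gene_i``/``gene_j`` or a 2-tuple of gene
    ids) is tested for bivariate normality and heteroscedasticity at
    ``alpha`` and flagged as multimodal when the BIC-selected mixture has
    K >= 2 components. Edges with fewer than 5 usable samples are skipped
    and counted.
    """
    rows = []
    n_skipped = 0
    for idx, edge in enumerate(edges):
        gi, gj = _edge_genes(edge)
        x = gem.row(gi)
        y = gem.row(gj)
        ok = np.isfinite(x) & np.isfinite(y)
        xs, ys = x[ok], y[ok]
        if outlier_removal and len(xs) >= 4:
            bad = tukey_mask(xs) | tukey_mask(ys)
            xs, ys = xs[~bad], ys[~bad]
        if len(xs) < 5 or len(xs) > 2000:
            n_skipped += 1
            continue
        roy_p = royston_normality(xs, ys)
        try:
            bp_p = breusch_pagan(xs, ys)
        except ValueError:
            n_skipped += 1
            continue
        k, _ = fit_pair_clusters(xs, ys, max_k=max_k,
                                 min_cluster_size=min_cluster_size,
                                 seed=seed + idx)
        rows.append({"gene_i": gi, "gene_j": gj, "n": len(xs),
                     "royston_p": roy_p, "bp_p": bp_p, "k": k})
    per_edge = pd.DataFrame(
        rows, columns=["gene_i", "gene_j", "n", "royston_p", "bp_p", "k"]
    )
    n = len(per_edge)
    if n == 0:
        return AuditReport(0, n_skipped, 0.0, 0.0, 0.0, 0.0, per_edge)
    fail_norm = per_edge["royston_p"] < alpha
    fail_var = per_edge["bp_p"] < alpha
    nonnormal = per_edge[fail_norm]
    multi = float((nonnormal["k"] >= 2).mean()) if len(nonnormal) else 0.0
    return AuditReport(
        n_edges_tested=n,
        n_skipped=n_skipped,
        fraction_failing_normality=float(fail_norm.mean()),
        fraction_failing_equal_variance=float(fail_var.mean()),
        fraction_failing_either=float((fail_norm | fail_var).mean()),
        fraction_multimodal_among_nonnormal=multi,
        per_edge=per_edge,
    )
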