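"""Per-pair outlier removal, mixture clustering and per-cluster correlation.

For every gene pair the engine (i) drops samples missing in either gene,
(ii) removes Tukey-fence outliers on each gene's marginal values, (iii) fits
bivariate Gaussian mixtures for k = 1..max_k and keeps the BIC-optimal model,
(iv) removes Tukey outliers within each cluster, and (v) scores each
surviving cluster with Pearson or Spearman correlation. Clusters whose
correlation magnitude falls below a minimum score are discarded (a screen
meant to bound output size, not a significance test).

Every sample's fate for a pair is encoded in a sample-state string with one
code per GEM sample:

* ``9`` — missing in at least one gene of the pair;
* ``6`` — removed as a pre-clustering outlier;
* ``7`` — removed at or after the clustering stage (cluster outlier,
  member of an undersized/degenerate cluster, or member of a cluster that
  failed the minimum-correlation screen);
* ``0``..``5`` — index of the retained cluster the sample belongs to.

The digit codes therefore count exactly the samples inside retained
clusters, so per pair the code counts always sum to the number of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from scipy import stats

from ._gmm import MixtureFit, fit_mixture
from .gem_io import GEM

logger = logging.getLogger(__name__)

MISSING_CODE = "9"
PRE_OUTLIER_CODE = "6"
CLUSTER_REMOVED_CODE = "7"

__all__ = [
    "SimilarityParams",
    "ClusterStats",
    "PairClusterResult",
    "tukey_mask",
    "fit_candidate_mixtures",
    "select_mixture",
    "fit_pair_clusters",
    "remove_cluster_outliers",
    "cluster_correlation",
    "similarity_pass",
    "pair_seed",
    "write_clusters",
    "read_clusters",
]


@dataclass(frozen=True)
class SimilarityParams:
    """Tunable knobs of the similarity pass.

    ``min_abs_correlation`` defaults to 0.5, the conventional storage screen;
    ``min_cluster_size`` defaults to 30 samples per retainable cluster.
    """

    method: str = "pearson"
    max_k: int = 5
    min_cluster_size: int = 30
    min_abs_correlation: float = 0.5
    tol: float = 1e-5
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation method {self.method!r}")
        if self.max_k < 1 or self.max_k > 6:
            raise ValueError("max_k must be in 1..6 (cluster codes are single digits)")
        if self.min_cluster_size < 3:
            raise ValueError("min_cluster_size must be >= 3")


@dataclass(frozen=True)
class ClusterStats:
    """One retained cluster of one gene pair."""

    index: int
    size: int
    method: str
    r: float


@dataclass
class PairClusterResult:
    """Disposition of every sample plus per-cluster correlations for a pair."""

    gene_i: str
    gene_j: str
    k: int
    states: str
    clusters: list[ClusterStats] = field(default_factory=list)

    def members(self, cluster_index: int) -> np.ndarray:
        """Boolean mask (over all GEM samples) of one cluster's members."""
        return np.frombuffer(self.states.encode(), dtype="S1") == str(
            cluster_index
        ).encode()


def tukey_mask(values: Iterable[float]) -> np.ndarray:
    """Flag values outside the Tukey fences Q1 - 1.5 IQR, Q3 + 1.5 IQR.

    Quartiles use linear interpolation (the type-7 convention). With fewer
    than 4 finite values no flags are raised and a warning is logged.
    """
    values = np.asarray(list(values), dtype=float)
    finite = np.isfinite(values)
    flags = np.zeros(values.shape, dtype=bool)
    if finite.sum() < 4:
        logger.warning("tukey_mask: fewer than 4 values, no outliers flagged")
        return flags
    q1, q3 = np.percentile(values[finite], [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flags[finite] = (values[finite] < lo) | (values[finite] > hi)
    return flags


def pair_seed(seed: int, i: int, j: int) -> int:
    """Deterministic per-pair seed, independent of evaluation order."""
    return int(np.random.SeedSequence([seed, i, j]).generate_state(1)[0]) & 0x7FFFFFFF


def fit_candidate_mixtures(x, y, max_k: int, seed: int, tol: float = 1e-5,
                           max_iter: int = 300) -> list[MixtureFit]:
    """Fit mixtures for k = 1..max_k; non-convergent fits are dropped (logged)."""
    X = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    fits = []
    for k in range(1, max_k + 1):
        fit = fit_mixture(X, k, seed + k, tol=tol, max_iter=max_iter)
        if not fit.converged:
            logger.debug("EM did not converge at k=%d (n=%d); skipped", k, len(X))
            continue
        fits.append(fit)
    return fits


def select_mixture(fits: list[MixtureFit], n: int) -> MixtureFit | None:
    """BIC-minimising fit among the candidates (ties favour smaller k)."""
    if not fits:
        return None
    return min(fits, key=lambda f: (f.bic(n), f.k))


def _reindex(labels: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Renumber clusters 0..K-1 by decreasing size; ties by lower mean x."""
    out = np.full(labels.shape, -1, dtype=int)
    present = [c for c in np.unique(labels) if c >= 0]
    keyed = sorted(
        present,
        key=lambda c: (-(labels == c).sum(), float(np.mean(x[labels == c]))),
    )
    for new, old in enumerate(keyed):
        out[labels == old] = new
    return out


def fit_pair_clusters(x, y, max_k: int = 5, min_cluster_size: int = 30,
                      seed: int = 0, tol: float = 1e-5,
                      max_iter: int = 300) -> tuple[int, np.ndarray]:
    """Cluster one pair's 2-D scatter with a BIC-selected Gaussian mixture.

    Returns ``(K, labels)`` where ``labels[s] = -1`` marks samples not in any
    retained cluster. Clusters smaller than ``min_cluster_size`` (by hard
    assignment) are dropped; remaining clusters are renumbered 0..K-1 by
    decreasing size, ties broken by lower mean x.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < min_cluster_size:
        return 0, np.full(n, -1, dtype=int)
    fits = fit_candidate_mixtures(x, y, max_k, seed, tol=tol, max_iter=max_iter)
    best = select_mixture(fits, n)
    if best is None:
        return 0, np.full(n, -1, dtype=int)
    labels = best.labels.astype(int)
    for c in range(best.k):
        if (labels == c).sum() < min_cluster_size:
            labels[labels == c] = -1
    labels = _reindex(labels, x)
    k = int(labels.max() + 1) if (labels >= 0).any() else 0
    return k, labels


def remove_cluster_outliers(x, y, labels, min_cluster_size: int = 30
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Apply Tukey fences within each cluster to x and y separately.

    Flagged samples leave their cluster; clusters that fall below
    ``min_cluster_size`` afterwards are dropped entirely. Returns the updated
    labels and the boolean mask of samples flagged as cluster outliers.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    labels = np.asarray(labels, int).copy()
    flagged = np.zeros(labels.shape, dtype=bool)
    for c in [c for c in np.unique(labels) if c >= 0]:
        members = labels == c
        bad = tukey_mask(x[members]) | tukey_mask(y[members])
        idx = np.flatnonzero(members)[bad]
        flagged[idx] = True
        labels[idx] = -1
        if (labels == c).sum() < min_cluster_size:
            labels[labels == c] = -1
    return labels, flagged


def cluster_correlation(x, y, labels, method: str = "pearson") -> dict[int, float]:
    """Pearson or Spearman correlation per retained cluster.

    Clusters with fewer than 3 samples or zero variance in either gene are
    excluded (logged) — their correlation is undefined.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    labels = np.asarray(labels, int)
    out: dict[int, float] = {}
    for c in [c for c in np.unique(labels) if c >= 0]:
        members = labels == c
        xs, ys = x[members], y[members]
        if members.sum() < 3:
            logger.debug("cluster %d has <3 samples; correlation undefined", c)
            continue
        if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
            logger.debug("cluster %d has zero variance; excluded", c)
            continue
        if method == "pearson":
            r = stats.pearsonr(xs, ys).statistic
        elif method == "spearman":
            r = stats.spearmanr(xs, ys).statistic
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        out[int(c)] = float(r)
    return out


def _pair_result(gem: GEM, i: int, j: int, params: SimilarityParams
                 ) -> PairClusterResult | None:
    x_all = gem.values[i]
    y_all = gem.values[j]
    n = gem.n_samples
    codes = np.full(n, CLUSTER_REMOVED_CODE, dtype=object)

    missing = np.isnan(x_all) | np.isnan(y_all)
    codes[missing] = MISSING_CODE
    complete = np.flatnonzero(~missing)
    if len(complete) < params.min_cluster_size:
        return None

    xc, yc = x_all[complete], y_all[complete]
    pre_out = tukey_mask(xc) | tukey_mask(yc)
    codes[complete[pre_out]] = PRE_OUTLIER_CODE
    kept = complete[~pre_out]
    if len(kept) < params.min_cluster_size:
        return None

    xk, yk = x_all[kept], y_all[kept]
    seed = pair_seed(params.seed, i, j)
    _, labels = fit_pair_clusters(
        xk, yk, max_k=params.max_k, min_cluster_size=params.min_cluster_size,
        seed=seed, tol=params.tol, max_iter=params.max_iter,
    )
    labels, _ = remove_cluster_outliers(xk, yk, labels, params.min_cluster_size)
    rs = cluster_correlation(xk, yk, labels, params.method)
    for c in list(rs):
        if abs(rs[c]) < params.min_abs_correlation:
            del rs[c]
    survivors = sorted(rs)
    if not survivors:
        return None
    keep = np.isin(labels, survivors)
    labels = np.where(keep, labels, -1)
    final = _reindex(labels, xk)
    clusters = []
    remap = {}
    for c in survivors:
        new = int(final[labels == c][0])
        remap[c] = new
    for c in survivors:
        new = remap[c]
        clusters.append(ClusterStats(index=new, size=int((final == new).sum()),
                                     method=params.method, r=rs[c]))
    clusters.sort(key=lambda cs: cs.index)
    for s, lab in zip(kept, final):
        if lab >= 0:
            codes[s] = str(lab)
    return PairClusterResult(
        gene_i=gem.gene_ids[i],
        gene_j=gem.gene_ids[j],
        k=len(clusters),
        states="".join(codes),
        clusters=clusters,
    )


def similarity_pass(gem: GEM, params: SimilarityParams,
                    stats_out: dict | None = None
                    ) -> Iterator[PairClusterResult]:
    """Run the per-pair pipeline over all gene pairs i < j (GEM row order).

    Yields one :class:`PairClusterResult` per pair with at least one cluster
    surviving the minimum-correlation screen. Deterministic for a given seed:
    per-pair seeds depend only on the global seed and the gene indices, so the
    output stream is identical run to run.
    """
    counts = {"pairs": 0, "skipped_too_few_samples": 0, "emitted": 0}
    for i in range(gem.n_genes):
        for j in range(i + 1, gem.n_genes):
            counts["pairs"] += 1
            res = _pair_result(gem, i, j, params)
            if res is None:
                counts["skipped_too_few_samples"] += 1
                continue
            counts["emitted"] += 1
            yield res
    if stats_out is not None:
        stats_out.update(counts)


CLUSTER_COLUMNS = ["gene_i", "gene_j", "cluster_index", "num_clusters",
                   "cluster_size", "method", "r", "states"]


def write_clusters(results: Iterable[PairClusterResult], path) -> None:
    """Write one row per retained cluster as tab-delimited text."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CLUSTER_COLUMNS) + "\n")
        for res in results:
            for cs in res.clusters:
                fh.write(
                    f"{res.gene_i}\t{res.gene_j}\t{cs.index}\t{res.k}\t"
                    f"{cs.size}\t{cs.method}\t{cs.r!r}\t{res.states}\n"
                )


def read_clusters(path) -> list[PairClusterResult]:
    """Inverse of :func:`write_clusters`; rows of a pair are regrouped."""
    results: dict[tuple[str, str], PairClusterResult] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CLUSTER_COLUMNS:
            raise ValueError(f"{path}: unexpected cluster-file header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rec = dict(zip(CLUSTER_COLUMNS, f))
            key = (rec["gene_i"], rec["gene_j"])
            if key not in results:
                results[key] = PairClusterResult(
                    gene_i=rec["gene_i"], gene_j=rec["gene_j"],
                    k=int(rec["num_clusters"]), states=rec["states"], clusters=[],
                )
            results[key].clusters.append(ClusterStats(
                index=int(rec["cluster_index"]), size=int(rec["cluster_size"]),
                method=rec["method"], r=float(rec["r"]),
            ))
    return list(results.values())
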