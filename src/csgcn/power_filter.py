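"""Power-analysis filter for per-cluster correlations.

A cluster's correlation is only kept if its sample count could support a
two-sided test of zero correlation at the requested Type I error rate and
power. The minimum sample size comes from the Fisher z-transform:

    n_min = ceil( ((z_{1-alpha/2} + z_{power}) / atanh(|r|))^2 + 3 )

where z_q is the standard-normal quantile and the "+3" is the usual
small-sample correction of the z-transform's variance 1/(n-3). With the
defaults (alpha = 0.001, power = 0.8) a correlation of 0.85 needs at least
14 samples — a cluster of 5 samples at r = 0.85 is underpowered and removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

from scipy.special import ndtri

from .pairwise_engine import ClusterStats, PairClusterResult

__all__ = ["PowerParams", "min_samples_for_correlation", "apply_power_filter"]


@dataclass(frozen=True)
class PowerParams:
    """Type I error rate and power of the zero-correlation test."""

    alpha: float = 0.001
    power: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must be in (0, 1)")


def min_samples_for_correlation(r: float, params: PowerParams = PowerParams()) -> int:
    """Minimum sample size to detect correlation magnitude ``r`` versus zero.

    Two-sided test at ``params.alpha`` with power ``params.power``.
    ``r`` must be strictly between 0 and 1.
    """
    if not 0.0 < r < 1.0:
        raise ValueError(f"correlation magnitude must be in (0, 1), got {r}")
    z_alpha = ndtri(1.0 - params.alpha / 2.0)
    z_power = ndtri(params.power)
    return math.ceil(((z_alpha + z_power) / math.atanh(r)) ** 2 + 3.0)


def apply_power_filter(clusters: Iterable[PairClusterResult],
                       params: PowerParams = PowerParams(),
                       stats_out: dict | None = None
                       ) -> Iterator[PairClusterResult]:
    """Drop clusters whose size is below the Fisher-z minimum for their |r|.

    Pairs left with no clusters are dropped entirely. The sample-state string
    is updated so that members of removed clusters carry the removed code,
    and surviving clusters keep their indices.
    """
    counts = {"clusters_in": 0, "clusters_out": 0, "pairs_out": 0}
    for res in clusters:
        keep: list[ClusterStats] = []
        dropped: list[int] = []
        for cs in res.clusters:
            counts["clusters_in"] += 1
            if cs.size >= min_samples_for_correlation(abs(cs.r), params):
                keep.append(cs)
            else:
                dropped.append(cs.index)
        if not keep:
            continue
        states = res.states
        if dropped:
            table = {str(c): "7" for c in dropped}
            states = "".join(table.get(ch, ch) for ch in states)
        counts["clusters_out"] += len(keep)
        counts["pairs_out"] += 1
        yield PairClusterResult(
            gene_i=res.gene_i, gene_j=res.gene_j, k=len(keep),
            states=states, clusters=keep,
        )
    if stats_out is not None:
        stats_out.update(counts)
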