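"""End-to-end orchestration of the csGCN construction pipeline.

One configuration object carries every stage's parameters (with the
conventional defaults: minimum |r| 0.5, power 0.8 at alpha 0.001, context
alpha 0.001, R-squared 0.3), and one call runs

    similarity pass -> power filter -> context tests -> ranking -> output,

recording the cluster/edge counts entering and leaving each stage. Output
files are plain TSV and contain no timestamps, so identical configuration
and seed reproduce them byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .context_tests import ContextThresholds, annotate_clusters
from .edge_ranking import EdgeRecord, rank_edges, write_network
from .gem_io import GEM, AnnotationTable, load_annotations, load_gem
from .pairwise_engine import SimilarityParams, similarity_pass, write_clusters
from .power_filter import PowerParams, apply_power_filter

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineRun", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline parameters plus input/output paths."""

    gem: str | None = None
    annotations: str | None = None
    out_prefix: str = "csgcn"
    quantitative_vars: list[str] = field(default_factory=list)
    # similarity pass
    method: str = "pearson"
    max_k: int = 5
    min_cluster_size: int = 30
    min_abs_correlation: float = 0.5
    # power filter
    power: float = 0.8
    power_alpha: float = 0.001
    # context tests
    assoc_alpha: float = 0.001
    min_r2: float = 0.3
    miss_alpha: float = 0.001
    confound_alpha: float = 0.001
    outgroup: str = "noncluster"
    comparison: str = "all"
    miss_retain: str = "similar"
    # audit default (used by the CLI audit command)
    audit_alpha: float = 0.01
    seed: int = 0

    def similarity_params(self) -> SimilarityParams:
        return SimilarityParams(
            method=self.method, max_k=self.max_k,
            min_cluster_size=self.min_cluster_size,
            min_abs_correlation=self.min_abs_correlation, seed=self.seed,
        )

    def power_params(self) -> PowerParams:
        return PowerParams(alpha=self.power_alpha, power=self.power)

    def context_thresholds(self) -> ContextThresholds:
        return ContextThresholds(
            assoc_alpha=self.assoc_alpha, min_r2=self.min_r2,
            miss_alpha=self.miss_alpha, confound_alpha=self.confound_alpha,
            outgroup=self.outgroup, comparison=self.comparison,
            miss_retain=self.miss_retain,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineRun:
    """Outputs and per-stage bookkeeping of one pipeline execution."""

    config: PipelineConfig
    edges: list[EdgeRecord]
    stage_counts: dict[str, int]
    cluster_file: str
    network_file: str
    minimal_file: str
    log_file: str


def run_pipeline(config: PipelineConfig, gem: GEM | None = None,
                 annotations: AnnotationTable | None = None) -> PipelineRun:
    """Run every stage on the configured (or given) inputs and write outputs.

    Produces ``<prefix>.clusters.tsv`` (similarity-pass clusters),
    ``<prefix>.network.tsv`` (full ranked edge table),
    ``<prefix>.cyto.tsv`` (minimal Cytoscape-loadable edge list) and
    ``<prefix>.log`` (per-stage counts).
    """
    if gem is None:
        if config.gem is None:
            raise ValueError("no GEM given: set config.gem or pass gem=")
        gem = load_gem(config.gem)
    if annotations is None:
        if config.annotations is None:
            raise ValueError("no annotations given: set config.annotations "
                             "or pass annotations=")
        annotations = load_annotations(
            config.annotations,
            {v: "quantitative" for v in config.quantitative_vars},
            gem=gem,
        )

    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    cluster_file = f"{prefix}.clusters.tsv"
    network_file = f"{prefix}.network.tsv"
    minimal_file = f"{prefix}.cyto.tsv"
    log_file = f"{prefix}.log"

    sim_stats: dict[str, int] = {}
    results = list(similarity_pass(gem, config.similarity_params(), sim_stats))
    write_clusters(results, cluster_file)

    pow_stats: dict[str, int] = {}
    powered = list(apply_power_filter(results, config.power_params(), pow_stats))

    ctx_stats: dict[str, int] = {}
    edges = list(annotate_clusters(powered, gem, annotations,
                                   config.context_thresholds(), ctx_stats))
    edges = rank_edges(edges)
    write_network(edges, network_file, format="full-tsv")
    write_network(edges, minimal_file, format="minimal-tsv")

    stage_counts = {
        "pairs_total": sim_stats.get("pairs", 0),
        "pairs_with_clusters": sim_stats.get("emitted", 0),
        "clusters_similarity": sum(r.k for r in results),
        "clusters_powered": pow_stats.get("clusters_out", 0),
        "associations_candidate": ctx_stats.get("assoc_candidates", 0),
        "associations_failed_missingness": ctx_stats.get("failed_missingness", 0),
        "associations_failed_confound": ctx_stats.get("failed_confound", 0),
        "edges_final": len(edges),
    }
    with open(log_file, "w", encoding="utf-8") as fh:
        for k, v in stage_counts.items():
            fh.write(f"{k}\t{v}\n")
    logger.info("pipeline finished: %s", stage_counts)
    return PipelineRun(config=config, edges=edges, stage_counts=stage_counts,
                       cluster_file=cluster_file, network_file=network_file,
                       minimal_file=minimal_file, log_file=log_file)
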