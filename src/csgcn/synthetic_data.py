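"""Synthetic multi-condition expression data with planted context structure.

The generator emulates a controlled multi-factor transcriptomics design —
two subspecies crossed with five treatments, sampled along a time course —
and plants gene pairs of known archetypes so the whole construction
pipeline can be scored against ground truth:

``bimodal-split``
    Two well-separated modes of co-expression, one per subspecies; the
    pair is correlated (shared latent factor) inside one subspecies only.
``category-specific``
    Co-expression and a moderate mean shift only inside the heat and
    heat-recovery treatments; elsewhere the genes are independent with
    overlapping values. A configurable number of these pairs realise their
    specificity through *missingness* instead: both genes are undetected
    outside the control treatment and share a latent factor within it
    (the "spoke" geometry).
``confounded``
    Gene A is a pure function of the time covariate; gene B follows time
    everywhere with an additional heat-specific offset. The heat cluster is
    genuinely correlated — but only through shared time, so gene A shows no
    heat response and the pipeline is expected to reject the association.
``basal-pair``
    Both genes track the time covariate in all samples (ubiquitous,
    clock-like expression). All basal genes share the same driver, so they
    also correlate across pairs by construction.
``null``
    Independent noise.

Expression is on a log-like scale around a base level of 5 so that outlier
fences behave as they would on a real log-transformed matrix. Values are
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .edge_ranking import EdgeRecord
from .gem_io import GEM, AnnotationTable

__all__ = ["SyntheticConfig", "PlantedPair", "ArchetypeRecovery",
           "RecoveryReport", "generate_dataset", "score_recovery",
           "write_truth", "read_truth", "ARCHETYPES"]

ARCHETYPES = ("bimodal-split", "category-specific", "confounded",
              "basal-pair", "null")


@dataclass(frozen=True)
class SyntheticConfig:
    """Design and archetype counts of one synthetic dataset.

    The default scenario is 300 samples (2 subspecies x 5 treatments x 30
    time points over 0..8 h) with 20 pairs of each archetype plus 5
    missingness-flavoured category-specific ("spoke") pairs.
    """

    n_per_cell: int = 30
    subspecies: tuple[str, ...] = ("indica", "japonica")
    treatments: tuple[str, ...] = ("control", "heat", "heat_recovery",
                                   "drought", "drought_recovery")
    time_max: float = 8.0
    n_bimodal: int = 20
    n_category: int = 20
    n_spoke: int = 5
    n_confounded: int = 20
    n_basal: int = 20
    n_null: int = 20
    noise_sd: float = 0.5
    base_level: float = 5.0
    missing_rate: float = 0.01
    n_genes: int | None = None     # None: exactly the planted genes
    spoke_time_driven: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_bimodal, self.n_category, self.n_spoke,
                  self.n_confounded, self.n_basal, self.n_null)
        if any(c < 0 for c in counts):
            raise ValueError("archetype counts must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must be in [0, 1)")
        if self.n_genes is not None and self.n_genes < 2 * self.n_pairs:
            raise ValueError(
                f"config plants {self.n_pairs} pairs needing {2 * self.n_pairs} "
                f"genes but allows only {self.n_genes}"
            )

    @property
    def n_pairs(self) -> int:
        return (self.n_bimodal + self.n_category + self.n_spoke
                + self.n_confounded + self.n_basal + self.n_null)

    @property
    def n_samples(self) -> int:
        return self.n_per_cell * len(self.subspecies) * len(self.treatments)


@dataclass(frozen=True)
class PlantedPair:
    """Ground truth for one planted gene pair."""

    gene_i: str
    gene_j: str
    archetype: str
    variable: str | None      # context variable, None for null pairs
    label: str | None         # context label, None for quantitative/null
    rho: float                # generating within-context correlation


def _design(config: SyntheticConfig):
    subs, treats, times = [], [], []
    grid = np.linspace(0.0, config.time_max, config.n_per_cell)
    for s in config.subspecies:
        for t in config.treatments:
            subs.extend([s] * config.n_per_cell)
            treats.extend([t] * config.n_per_cell)
            times.extend(grid)
    return (np.array(subs, object), np.array(treats, object),
            np.array(times, float))


def generate_dataset(config: SyntheticConfig
                     ) -> tuple[GEM, AnnotationTable, list[PlantedPair]]:
    """Generate (GEM, annotations, planted truth); deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    subs, treats, times = _design(config)
    n = config.n_samples
    base = config.base_level
    sd = config.noise_sd
    tc = times - times.mean()

    genes: list[str] = []
    rows: list[np.ndarray] = []
    truth: list[PlantedPair] = []

    def add_pair(name_a, name_b, a, b, archetype, variable, label, rho):
        genes.extend([name_a, name_b])
        rows.extend([a, b])
        truth.append(PlantedPair(name_a, name_b, archetype, variable, label, rho))

    # bimodal-split: two modes >=4 sd apart, correlated inside indica only
    in_indica = subs == config.subspecies[0]
    for p in range(config.n_bimodal):
        s = rng.normal(0.0, 1.0, n)
        a = np.where(in_indica, base + s + rng.normal(0.0, sd, n),
                     base + 5.0 + rng.normal(0.0, 1.0, n))
        b = np.where(in_indica, base + s + rng.normal(0.0, sd, n),
                     base + 5.0 + rng.normal(0.0, 1.0, n))
        add_pair(f"bimodal{p:02d}_a", f"bimodal{p:02d}_b", a, b,
                 "bimodal-split", "Subspecies", config.subspecies[0],
                 1.0 / (1.0 + sd ** 2))

    # category-specific: co-expression plus moderate shift inside the heat
    # and heat-recovery treatments (the stress block), independent elsewhere.
    # Spanning two of the five treatments keeps the co-expressed mode a large
    # enough minority that the pairwise Tukey fences do not clip it away.
    in_heat = treats == "heat"
    in_stress = in_heat | (treats == "heat_recovery")
    for p in range(config.n_category):
        s = rng.normal(0.0, 1.0, n)
        eps = 1.0 / 3.0   # rho = 1/(1+eps^2) ~ 0.9
        a = np.where(in_stress, base + 2.0 + s + rng.normal(0.0, eps, n),
                     base + rng.normal(0.0, sd, n))
        b = np.where(in_stress, base + 2.0 + s + rng.normal(0.0, eps, n),
                     base + rng.normal(0.0, sd, n))
        add_pair(f"catspec{p:02d}_a", f"catspec{p:02d}_b", a, b,
                 "category-specific", "Treatment", "heat|heat_recovery", 0.9)

    # spoke flavour: undetected outside control, co-expressed within it
    in_control = treats == "control"
    for p in range(config.n_spoke):
        if config.spoke_time_driven:
            sig = 0.6 * tc
        else:
            sig = rng.normal(0.0, 1.0, n)
        a = np.where(in_control, base + sig + rng.normal(0.0, 1.0 / 3.0, n), np.nan)
        b = np.where(in_control, base + sig + rng.normal(0.0, 1.0 / 3.0, n), np.nan)
        add_pair(f"spoke{p:02d}_a", f"spoke{p:02d}_b", a, b,
                 "category-specific", "Treatment", "control", 0.9)

    # confounded: A is a pure function of time; B follows time everywhere
    # with an extra heat-specific offset and slope. The pair is genuinely
    # correlated inside the heat cluster, but only through the shared time
    # covariate — gene A shows no heat response, so the heat association is
    # expected to die at the per-gene differential-expression screen. B's
    # basal trend keeps its heat mode inside the pair's Tukey fences.
    for p in range(config.n_confounded):
        a = base + 0.5 * tc + rng.normal(0.0, 0.3, n)
        b = (base + 0.25 * tc + rng.normal(0.0, 0.3, n)
             + np.where(in_heat, 2.0 - 0.1 * tc, 0.0))
        add_pair(f"confounded{p:02d}_a", f"confounded{p:02d}_b", a, b,
                 "confounded", "Treatment", "heat", 0.74)

    # basal-pair: both genes track time in all samples (shared driver)
    for p in range(config.n_basal):
        a = base + 0.45 * tc + rng.normal(0.0, 0.35, n)
        b = base + 0.40 * tc + rng.normal(0.0, 0.35, n)
        add_pair(f"basal{p:02d}_a", f"basal{p:02d}_b", a, b,
                 "basal-pair", "Time", None, 0.88)

    # null: independent noise
    for p in range(config.n_null):
        a = base + rng.normal(0.0, sd, n)
        b = base + rng.normal(0.0, sd, n)
        add_pair(f"null{p:02d}_a", f"null{p:02d}_b", a, b,
                 "null", None, None, 0.0)

    # optional unplanted background genes
    if config.n_genes is not None:
        for g in range(config.n_genes - len(genes)):
            genes.append(f"background{g:03d}")
            rows.append(base + rng.normal(0.0, sd, n))

    values = np.vstack(rows)
    if config.missing_rate > 0.0:
        drop = rng.random(values.shape) < config.missing_rate
        values = np.where(drop, np.nan, values)

    sample_ids = [f"S{i:03d}" for i in range(n)]
    gem = GEM(gene_ids=genes, sample_ids=sample_ids, values=values)
    table = AnnotationTable(
        sample_ids=sample_ids,
        categorical={"Subspecies": subs, "Treatment": treats},
        quantitative={"Time": times},
    )
    return gem, table, truth


_TRUTH_COLUMNS = ["gene_i", "gene_j", "archetype", "variable", "label", "rho"]


def write_truth(truth: Iterable[PlantedPair], path) -> None:
    """Write the planted-pair truth table as tab-delimited text."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for t in truth:
            fh.write(f"{t.gene_i}\t{t.gene_j}\t{t.archetype}\t"
                     f"{t.variable or 'NA'}\t{t.label or 'NA'}\t{t.rho:.10g}\n")


def read_truth(path) -> list[PlantedPair]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TRUTH_COLUMNS:
            raise ValueError(f"{path}: unexpected truth-file header {header}")
        for line in fh:
            gi, gj, arch, var, lab, rho = line.rstrip("\n").split("\t")
            out.append(PlantedPair(gi, gj, arch,
                                   None if var == "NA" else var,
                                   None if lab == "NA" else lab, float(rho)))
    return out


def _matches(item: PlantedPair, edge: EdgeRecord) -> bool:
    if {edge.gene_i, edge.gene_j} != {item.gene_i, item.gene_j}:
        return False
    if item.variable is None:
        return False
    if edge.variable != item.variable:
        return False
    if item.label is None:
        return True
    # a planted context may span several labels (e.g. "heat|heat_recovery")
    return edge.label in item.label.split("|")


@dataclass
class ArchetypeRecovery:
    """Recovery metrics for one archetype's planted pairs."""

    n_pairs: int
    n_recovered: int
    n_edges: int          # edges whose pair is planted with this archetype
    n_matching: int
    zero_denominator: bool
    n_pairs_with_edges: int = 0

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_pairs if self.n_pairs else 0.0

    @property
    def precision(self) -> float:
        # precision over the archetype's emitted edges; an empty denominator
        # reports 1.0 with the zero_denominator flag set
        return self.n_matching / self.n_edges if self.n_edges else 1.0

    @property
    def pair_edge_rate(self) -> float:
        return self.n_pairs_with_edges / self.n_pairs if self.n_pairs else 0.0


@dataclass
class RecoveryReport:
    per_archetype: dict[str, ArchetypeRecovery]
    n_edges_total: int
    n_unplanted_edges: int


def score_recovery(truth: Iterable[PlantedPair],
                   network: Iterable[EdgeRecord]) -> RecoveryReport:
    """Score a network against planted truth, per archetype.

    A planted pair is recovered when some edge carries the pair with its
    true context (variable and, for categorical contexts, label). Edges on
    planted pairs count toward that archetype's precision; edges between
    genes that do not form a planted pair (e.g. cross-pair co-expression of
    genes sharing a driver) are tallied separately as unplanted.
    """
    truth = list(truth)
    network = list(network)
    by_pair = {frozenset((t.gene_i, t.gene_j)): t for t in truth}
    stats: dict[str, ArchetypeRecovery] = {
        a: ArchetypeRecovery(0, 0, 0, 0, False) for a in ARCHETYPES
    }
    pairs_with_edges: dict[frozenset, bool] = {}
    recovered: set[frozenset] = set()
    n_unplanted = 0
    for e in network:
        key = frozenset((e.gene_i, e.gene_j))
        t = by_pair.get(key)
        if t is None:
            n_unplanted += 1
            continue
        s = stats[t.archetype]
        s.n_edges += 1
        pairs_with_edges[key] = True
        if _matches(t, e):
            s.n_matching += 1
            recovered.add(key)
    for t in truth:
        s = stats[t.archetype]
        s.n_pairs += 1
        key = frozenset((t.gene_i, t.gene_j))
        if key in recovered:
            s.n_recovered += 1
        if pairs_with_edges.get(key):
            s.n_pairs_with_edges += 1
    for s in stats.values():
        s.zero_denominator = s.n_edges == 0
    return RecoveryReport(per_archetype=stats, n_edges_total=len(network),
                          n_unplanted_edges=n_unplanted)
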