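"""Assembling retained (cluster, context) records into a ranked csGCN.

Each edge is one retained cluster annotated with one experimental context;
a gene pair may therefore carry several edges, one per context, and no
global correlation threshold is applied to the multi-edge network. Edges
are ordered by a composite valuation combining the correlation magnitude,
the weakest context p-value and (for quantitative contexts) the mean R²:

    rank_score = |r| * min(-log10(p_ctx), 20) / 20 * q

with p_ctx = max(p_in, p_out) for categorical contexts or the larger of the
two per-gene slope p-values for quantitative ones, and q = mean per-gene R²
(quantitative) or 1 (categorical). The exact functional form of the
valuation is this package's own choice — the ingredients (score, test
p-values, R²) are standard, the combination is a documented stand-in (see
docs/methods.md). The -log10 cap at 20 keeps scores finite at p = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

__all__ = ["EdgeRecord", "rank_score", "rank_edges",
           "write_network", "read_network", "NETWORK_COLUMNS"]

_LOG10_CAP = 20.0


@dataclass
class EdgeRecord:
    """One context-specific network edge (a retained cluster x context)."""

    gene_i: str
    gene_j: str
    cluster_index: int
    num_clusters: int
    cluster_size: int
    method: str
    r: float
    variable: str
    kind: str                      # "categorical" | "quantitative"
    label: str | None = None       # categorical contexts only
    p_in: float | None = None
    p_out: float | None = None
    r2_i: float | None = None
    r2_j: float | None = None
    p_slope_i: float | None = None
    p_slope_j: float | None = None
    missingness_p: float | None = None
    confound_p_i: float | None = None
    confound_p_j: float | None = None
    states: str = ""
    rank_score: float | None = None
    rank: int | None = None
    extras: dict[str, str] = field(default_factory=dict)

    @property
    def context(self) -> str:
        """Human-readable context key, e.g. ``Treatment=heat`` or ``Time``."""
        if self.kind == "categorical":
            return f"{self.variable}={self.label}"
        return self.variable

    @property
    def p_context(self) -> float:
        """The weakest (largest) of the record's context-association p-values."""
        if self.kind == "categorical":
            return max(self.p_in, self.p_out)
        return max(self.p_slope_i, self.p_slope_j)


def rank_score(edge: EdgeRecord) -> float:
    p = edge.p_context
    neglog = _LOG10_CAP if p <= 0.0 else min(-math.log10(p), _LOG10_CAP)
    q = 1.0
    if edge.kind == "quantitative":
        q = 0.5 * (edge.r2_i + edge.r2_j)
    return abs(edge.r) * (neglog / _LOG10_CAP) * q


def rank_edges(edges: Iterable[EdgeRecord]) -> list[EdgeRecord]:
    """Score, sort (descending) and number the edges 1..n.

    Ties in score are broken lexicographically by
    (gene_i, gene_j, cluster_index, context) so the order is a deterministic
    total order.
    """
    edges = list(edges)
    for e in edges:
        e.rank_score = rank_score(e)
    edges.sort(key=lambda e: (-e.rank_score, e.gene_i, e.gene_j,
                              e.cluster_index, e.context))
    for pos, e in enumerate(edges, start=1):
        e.rank = pos
    return edges


NETWORK_COLUMNS = [
    "gene_i", "gene_j", "cluster_index", "num_clusters", "cluster_size",
    "method", "r", "variable", "kind", "label", "p_in", "p_out",
    "r2_i", "r2_j", "p_slope_i", "p_slope_j", "missingness_p",
    "confound_p_i", "confound_p_j", "states", "rank_score", "rank",
]

_FLOAT_FIELDS = {"r", "p_in", "p_out", "r2_i", "r2_j", "p_slope_i",
                 "p_slope_j", "missingness_p", "confound_p_i",
                 "confound_p_j", "rank_score"}
_INT_FIELDS = {"cluster_index", "num_clusters", "cluster_size", "rank"}


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return str(v)   # shortest round-trip representation
    return str(v)


def write_network(edges: list[EdgeRecord], path, format: str = "full-tsv") -> None:
    """Write the ranked network as tab-delimited text.

    ``full-tsv`` carries every edge field in a fixed column order (plus any
    extra attributes, appended alphabetically); ``minimal-tsv`` is a
    4-column source/target/score/context table suitable for Cytoscape import.
    """
    if format == "minimal-tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tscore\tcontext\n")
            for e in edges:
                fh.write(f"{e.gene_i}\t{e.gene_j}\t{_fmt(e.rank_score)}\t{e.context}\n")
        return
    if format != "full-tsv":
        raise ValueError(f"unknown network format {format!r}")
    extra_cols = sorted({k for e in edges for k in e.extras})
    cols = NETWORK_COLUMNS + extra_cols
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for e in edges:
            row = [_fmt(getattr(e, c)) for c in NETWORK_COLUMNS]
            row += [_fmt(e.extras.get(k)) for k in extra_cols]
            fh.write("\t".join(row) + "\n")


def _parse(field_name: str, raw: str):
    if raw == "NA":
        return None
    if field_name in _FLOAT_FIELDS:
        return float(raw)
    if field_name in _INT_FIELDS:
        return int(raw)
    return raw


def read_network(path) -> list[EdgeRecord]:
    """Read a full-tsv network file back into edge records.

    Unknown extra columns are preserved as opaque string attributes; a
    missing required column raises an error naming it.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in NETWORK_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        extra_cols = [c for c in header if c not in NETWORK_COLUMNS]
        edges = []
        for line in fh:
            raw = dict(zip(header, line.rstrip("\n").split("\t")))
            kwargs = {c: _parse(c, raw[c]) for c in NETWORK_COLUMNS}
            kwargs["states"] = kwargs["states"] or ""
            extras = {c: raw[c] for c in extra_cols if raw[c] != "NA"}
            edges.append(EdgeRecord(**kwargs, extras=extras))
    return edges
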