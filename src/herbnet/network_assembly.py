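"""Tripartite herb-compound-target network assembly and disease-gene overlap.

Compounds are filtered by a drug-likeness (QED) cutoff and compound-target
interactions by a confidence cutoff; both are strict inequalities, so boundary
values are excluded.  The surviving records form a three-layer network with
edges only between adjacent layers.  Two disease-gene sources (one curated
"direct evidence" list, one carrying a gene-disease association score) are
merged, and per-herb overlap tables between predicted targets and disease
genes are computed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "InteractionRecord",
    "DiseaseGeneRecord",
    "TripartiteNetwork",
    "OverlapTable",
    "MergeMode",
    "filter_druglike",
    "filter_confident",
    "build_network",
    "merge_disease_genes",
    "elbow_threshold",
    "overlap_with_disease",
    "read_compound_table",
    "read_interaction_table",
    "read_disease_gene_table",
]


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    herb_id: str
    qed: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.qed <= 1.0:
            raise ValueError(
                f"qed out of [0,1] for compound {self.compound_id!r} "
                f"(herb {self.herb_id!r}): {self.qed}"
            )


@dataclass(frozen=True)
class InteractionRecord:
    compound_id: str
    target_gene: str
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(
                f"confidence out of [0,1] for interaction "
                f"({self.compound_id!r}, {self.target_gene!r}): {self.confidence}"
            )


class GeneSource(str, Enum):
    direct_evidence = "direct_evidence"
    scored = "scored"


@dataclass(frozen=True)
class DiseaseGeneRecord:
    gene: str
    source: GeneSource
    gda_score: float | None = None

    def __post_init__(self) -> None:
        src = GeneSource(self.source)
        object.__setattr__(self, "source", src)
        if src is GeneSource.scored and self.gda_score is None:
            raise ValueError(f"scored record for {self.gene!r} lacks a gda_score")


class MergeMode(str, Enum):
    intersection = "intersection"
    union = "union"


@dataclass
class TripartiteNetwork:
    """Three-layer herb -> compound -> target network after filtering.

    `herbs` keeps every herb supplied at build time, including herbs whose
    compounds were all filtered out (they appear with zero edges, mirroring
    how bookkeeping tables report such herbs).
    """

    herb_compound_edges: frozenset[tuple[str, str]]
    compound_target_edges: frozenset[tuple[str, str]]
    herbs: tuple[str, ...]

    @property
    def compounds(self) -> frozenset[str]:
        return frozenset(c for _, c in self.herb_compound_edges)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(t for _, t in self.compound_target_edges)

    def compounds_of(self, herb: str) -> frozenset[str]:
        return frozenset(c for h, c in self.herb_compound_edges if h == herb)

    def targets_of(self, herb: str) -> frozenset[str]:
        cps = self.compounds_of(herb)
        return frozenset(t for c, t in self.compound_target_edges if c in cps)

    def edge_counts(self) -> pd.DataFrame:
        """Per-herb H-C and C-T edge counts (bookkeeping-table columns)."""
        rows = []
        ct_by_compound = Counter(c for c, _ in self.compound_target_edges)
        for herb in self.herbs:
            cps = self.compounds_of(herb)
            rows.append(
                {
                    "herb_id": herb,
                    "n_hc": len(cps),
                    "n_ct": sum(ct_by_compound[c] for c in cps),
                }
            )
        return pd.DataFrame(rows)

    def to_networkx(self) -> nx.Graph:
        """Graph with a `layer` node attribute, suitable for GraphML/GEXF export."""
        g = nx.Graph()
        for herb in self.herbs:
            g.add_node(f"herb::{herb}", layer="herb", label=herb)
        for herb, comp in sorted(self.herb_compound_edges):
            g.add_node(f"compound::{comp}", layer="compound", label=comp)
            g.add_edge(f"herb::{herb}", f"compound::{comp}")
        for comp, tgt in sorted(self.compound_target_edges):
            g.add_node(f"target::{tgt}", layer="target", label=tgt)
            g.add_edge(f"compound::{comp}", f"target::{tgt}")
        return g

    def write(self, prefix: str) -> None:
        g = self.to_networkx()
        nx.write_graphml(g, f"{prefix}.graphml")
        nx.write_gexf(g, f"{prefix}.gexf")


@dataclass
class OverlapTable:
    """Per-herb overlap between predicted targets and a disease gene set."""

    per_herb_gene_counts: dict[str, dict[str, int]]
    disease_genes: frozenset[str]
    herbs: tuple[str, ...] = field(default_factory=tuple)

    def overlapped_genes(self, herb: str) -> frozenset[str]:
        return frozenset(self.per_herb_gene_counts.get(herb, {}))

    def total_interactions(self, herb: str) -> int:
        return sum(self.per_herb_gene_counts.get(herb, {}).values())

    @property
    def n_herbs_with_overlap(self) -> int:
        return sum(1 for h in self.herbs if self.per_herb_gene_counts.get(h))

    def gene_herb_degree(self) -> pd.Series:
        """For each disease gene hit, the number of herbs targeting it (ranking)."""
        deg = Counter(
            g for counts in self.per_herb_gene_counts.values() for g in counts
        )
        s = pd.Series(deg, dtype=int)
        return s.sort_values(ascending=False, kind="stable")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for herb in self.herbs:
            counts = self.per_herb_gene_counts.get(herb, {})
            detail = ", ".join(
                f"{g}({c})" if c > 1 else g for g, c in sorted(counts.items())
            )
            rows.append(
                {
                    "herb_id": herb,
                    "n_overlapped_genes": len(counts),
                    "n_overlap_interactions": sum(counts.values()),
                    "overlapped_genes": detail or "-",
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Filtering


def filter_druglike(
    compounds: list[CompoundRecord], cutoff: float = 0.35
) -> list[CompoundRecord]:
    """Keep compounds with QED strictly above `cutoff`."""
    kept = [c for c in compounds if c.qed > cutoff]
    logger.info("QED filter (> %g): %d -> %d compounds", cutoff, len(compounds), len(kept))
    return kept


def filter_confident(
    interactions: list[InteractionRecord], cutoff: float = 0.7
) -> list[InteractionRecord]:
    """Keep interactions with confidence strictly above `cutoff`."""
    kept = [i for i in interactions if i.confidence > cutoff]
    logger.info(
        "confidence filter (> %g): %d -> %d interactions",
        cutoff,
        len(interactions),
        len(kept),
    )
    return kept


# ---------------------------------------------------------------------------
# Assembly


def build_network(
    compounds: list[CompoundRecord],
    interactions: list[InteractionRecord],
    herbs: list[str] | None = None,
) -> TripartiteNetwork:
    """Assemble the tripartite network from filtered records.

    Interactions whose compound does not appear in the (filtered) compound
    table are dropped with a warning — database exports routinely contain
    orphans.  Pass `herbs` to keep herbs that lost every compound to the
    QED filter in the layer index.
    """
    hc = frozenset((c.herb_id, c.compound_id) for c in compounds)
    known = {c for _, c in hc}
    kept, orphans = [], 0
    for rec in interactions:
        if rec.compound_id in known:
            kept.append((rec.compound_id, rec.target_gene))
        else:
            orphans += 1
    if orphans:
        logger.warning("dropped %d interactions referencing unknown compounds", orphans)
    herb_index = tuple(herbs) if herbs is not None else tuple(
        sorted({h for h, _ in hc})
    )
    return TripartiteNetwork(
        herb_compound_edges=hc,
        compound_target_edges=frozenset(kept),
        herbs=herb_index,
    )


def merge_disease_genes(
    records: list[DiseaseGeneRecord],
    gda_cutoff: float = 0.3,
    mode: MergeMode | str = MergeMode.intersection,
) -> frozenset[str]:
    """Merge direct-evidence and score-filtered disease genes.

    Scored records are first filtered to gda_score strictly above
    `gda_cutoff`.  `intersection` (default) keeps genes present in both
    sources; `union` keeps genes present in either.
    """
    mode = MergeMode(mode)
    direct = {r.gene for r in records if r.source is GeneSource.direct_evidence}
    scored = {
        r.gene
        for r in records
        if r.source is GeneSource.scored and r.gda_score > gda_cutoff
    }
    result = direct & scored if mode is MergeMode.intersection else direct | scored
    if not result:
        logger.warning("disease-gene merge (%s) produced an empty set", mode.value)
    return frozenset(result)


def elbow_threshold(scores: list[float]) -> float:
    """Knee of a sorted-descending score curve.

    Returns the score at the index maximizing perpendicular distance from the
    (rank, score) curve to the chord joining its endpoints; ties break to the
    smallest index.  Degenerate (collinear) curves return the first interior
    point with a warning.
    """
    vals = np.asarray(scores, dtype=float)
    if vals.size < 3:
        raise ValueError("elbow undefined: need at least 3 points")
    if np.any(np.diff(vals) > 0):
        raise ValueError("scores must be sorted descending")
    n = len(vals)
    x = np.arange(n, dtype=float)
    # perpendicular distance from each point to the first-last chord
    x0, y0, x1, y1 = 0.0, vals[0], float(n - 1), vals[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x0) - dx * (vals - y0)) / norm
    interior = dist[1:-1]
    if np.all(interior == 0):
        logger.warning("elbow degenerate: scores are collinear")
        return float(vals[1])
    idx = 1 + int(np.argmax(interior))
    return float(vals[idx])


def overlap_with_disease(
    network: TripartiteNetwork, disease_genes: frozenset[str] | set[str]
) -> OverlapTable:
    """Per-herb counts of compound-target interactions hitting disease genes.

    An herb's count for gene g is the number of its compounds' C-T edges to g
    (multiple compounds of one herb hitting the same gene count separately).
    """
    disease_genes = frozenset(disease_genes)
    per_herb: dict[str, dict[str, int]] = {}
    for herb in network.herbs:
        cps = network.compounds_of(herb)
        counts: Counter = Counter(
            t
            for c, t in network.compound_target_edges
            if c in cps and t in disease_genes
        )
        if counts:
            per_herb[herb] = dict(counts)
    return OverlapTable(
        per_herb_gene_counts=per_herb,
        disease_genes=disease_genes,
        herbs=network.herbs,
    )


# ---------------------------------------------------------------------------
# I/O


def read_compound_table(path: str) -> list[CompoundRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        CompoundRecord(compound_id=str(r.compound_id), herb_id=str(r.herb_id), qed=float(r.qed))
        for r in df.itertuples()
    ]


def read_interaction_table(path: str) -> list[InteractionRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        InteractionRecord(
            compound_id=str(r.compound_id),
            target_gene=str(r.target_gene),
            confidence=float(r.confidence),
        )
        for r in df.itertuples()
    ]


def read_disease_gene_table(path: str) -> list[DiseaseGeneRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for r in df.itertuples():
        score = getattr(r, "gda_score", None)
        if score is not None and pd.isna(score):
            score = None
        records.append(
            DiseaseGeneRecord(
                gene=str(r.gene),
                source=GeneSource(str(r.source)),
                gda_score=None if score is None else float(score),
            )
        )
    return records
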