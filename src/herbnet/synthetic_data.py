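"""Synthetic input generators with planted, recorded ground truth.

Every pipeline input — prescription corpus, herb-compound tables with
drug-likeness scores, compound-target interactions with confidences,
two-source disease-gene tables, gene-set libraries, and PPI graphs — can be
generated here with known planted structure (disease-specific herbs, herb
groups sharing target pools, enriched terms, assortative blocks).  Each
generator is a pure function of its parameters and a seed, and returns a
:class:`SyntheticTruth` alongside the data so downstream stages can be
checked against what was planted.

A single root seed fans out to per-generator streams through
``numpy.random.SeedSequence([seed, salt])`` with a fixed per-generator salt,
so an end-to-end dataset is reproducible from one integer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus_specificity import PrescriptionCorpus
from .enrichment import GeneSetLibrary, write_gmt
from .network_assembly import CompoundRecord, DiseaseGeneRecord, GeneSource, InteractionRecord

__all__ = [
    "SyntheticTruth",
    "generate_prescription_corpus",
    "generate_compound_tables",
    "generate_interactions",
    "generate_disease_genes",
    "generate_geneset_library",
    "generate_ppi_sbm",
    "generate_all",
]

# per-generator salts for SeedSequence fan-out
_SALTS = {
    "corpus": 1,
    "compounds": 2,
    "interactions": 3,
    "disease_genes": 4,
    "library": 5,
    "ppi": 6,
}


def _rng(seed: int, salt_key: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _SALTS[salt_key]]))


@dataclass
class SyntheticTruth:
    """What a generator planted, serializable next to the data it describes."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    data: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            if isinstance(o, np.integer):
                return int(o)
            if isinstance(o, np.floating):
                return float(o)
            raise TypeError(f"not serializable: {type(o)}")

        Path(path).write_text(
            json.dumps(
                {"kind": self.kind, "seed": self.seed, "params": self.params, "data": self.data},
                indent=2,
                sort_keys=True,
                default=default,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(kind=d["kind"], seed=d["seed"], params=d["params"], data=d["data"])


def _herb_id(i: int) -> str:
    return f"hrb{i:04d}"


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


# ---------------------------------------------------------------------------
# Corpus


def generate_prescription_corpus(
    n_background: int = 500,
    n_representative: int = 12,
    n_herbs: int = 200,
    n_specific: int = 10,
    p_specific_in_rep: float = 0.9,
    p_specific_in_bg: float = 0.02,
    mean_herbs_per_rx: int = 12,
    seed: int = 0,
) -> tuple[PrescriptionCorpus, SyntheticTruth]:
    """Corpus with planted disease-specific herbs.

    Specific herbs enter each representative prescription with probability
    `p_specific_in_rep` and each background prescription with
    `p_specific_in_bg`; the remaining slots (up to `mean_herbs_per_rx` herbs
    per prescription) are filled uniformly from the non-specific pool.
    """
    if n_specific > n_herbs:
        raise ValueError("n_specific exceeds n_herbs")
    for name, p in (("p_specific_in_rep", p_specific_in_rep), ("p_specific_in_bg", p_specific_in_bg)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} must lie in (0,1), got {p}")
    if p_specific_in_rep <= p_specific_in_bg:
        raise ValueError("p_specific_in_rep must exceed p_specific_in_bg")
    rng = _rng(seed, "corpus")
    specific = [_herb_id(i) for i in range(1, n_specific + 1)]
    fillers = [_herb_id(i) for i in range(n_specific + 1, n_herbs + 1)]

    def make_rx(p_specific: float) -> list[str]:
        herbs = [h for h in specific if rng.random() < p_specific]
        n_fill = max(mean_herbs_per_rx - len(herbs), 0)
        herbs += list(rng.choice(fillers, size=n_fill, replace=False))
        if not herbs:
            herbs = [fillers[int(rng.integers(len(fillers)))]]
        return herbs

    prescriptions: dict[str, list[str]] = {}
    rep_ids = []
    for i in range(1, n_representative + 1):
        pid = f"RX_R{i:03d}"
        prescriptions[pid] = make_rx(p_specific_in_rep)
        rep_ids.append(pid)
    for i in range(1, n_background + 1):
        prescriptions[f"RX_B{i:04d}"] = make_rx(p_specific_in_bg)

    corpus = PrescriptionCorpus(prescriptions=prescriptions, representative_ids=rep_ids)
    truth = SyntheticTruth(
        kind="prescription_corpus",
        seed=seed,
        params={
            "n_background": n_background,
            "n_representative": n_representative,
            "n_herbs": n_herbs,
            "n_specific": n_specific,
            "p_specific_in_rep": p_specific_in_rep,
            "p_specific_in_bg": p_specific_in_bg,
            "mean_herbs_per_rx": mean_herbs_per_rx,
        },
        data={"planted_specific_herbs": sorted(specific)},
    )
    return corpus, truth


# ---------------------------------------------------------------------------
# Compounds


def generate_compound_tables(
    herbs: list[str],
    compounds_per_herb: tuple[int, int] = (6, 40),
    qed_alpha: float = 2.0,
    qed_beta: float = 2.0,
    seed: int = 0,
) -> tuple[list[CompoundRecord], SyntheticTruth]:
    """Per-herb compound lists with Beta-distributed drug-likeness scores."""
    if qed_alpha <= 0 or qed_beta <= 0:
        raise ValueError("Beta parameters must be positive")
    lo, hi = compounds_per_herb
    if lo < 1 or hi < lo:
        raise ValueError(f"bad compounds_per_herb range: {compounds_per_herb}")
    rng = _rng(seed, "compounds")
    records: list[CompoundRecord] = []
    pass_counts: dict[str, int] = {}
    idx = 0
    for herb in herbs:
        n = int(rng.integers(lo, hi + 1))
        qeds = rng.beta(qed_alpha, qed_beta, size=n)
        passing = 0
        for q in qeds:
            idx += 1
            records.append(
                CompoundRecord(compound_id=f"CPD{idx:05d}", herb_id=herb, qed=float(q))
            )
            if q > 0.35:
                passing += 1
        pass_counts[herb] = passing
    truth = SyntheticTruth(
        kind="compound_tables",
        seed=seed,
        params={
            "compounds_per_herb": list(compounds_per_herb),
            "qed_alpha": qed_alpha,
            "qed_beta": qed_beta,
        },
        data={"n_passing_qed_035": pass_counts},
    )
    return records, truth


# ---------------------------------------------------------------------------
# Interactions


def generate_interactions(
    compounds: list[CompoundRecord],
    n_targets: int = 300,
    herb_groups: dict[str, int] | None = None,
    p_within_group_target: float = 0.3,
    p_background_target: float = 0.01,
    confidence_high: float = 0.9,
    confidence_low: float = 0.5,
    seed: int = 0,
) -> tuple[list[InteractionRecord], SyntheticTruth]:
    """Compound-target interactions planting shared target pools per herb group.

    The target universe is split into one disjoint pool per herb group plus a
    shared background pool.  A compound of a group-g herb hits each gene of
    pool g with probability `p_within_group_target` (confidence
    `confidence_high`) and each background-pool gene with
    `p_background_target` (confidence `confidence_low`).  With the defaults
    the high-confidence edges are exactly the planted within-group structure.
    """
    if p_within_group_target <= p_background_target:
        raise ValueError("p_within_group_target must exceed p_background_target")
    if herb_groups is None:
        herb_groups = {h: 0 for h in {c.herb_id for c in compounds}}
    groups = sorted(set(herb_groups.values()))
    n_groups = len(groups)
    rng = _rng(seed, "interactions")
    targets = [_gene_id(i) for i in range(1, n_targets + 1)]
    pool_size = n_targets // (n_groups + 1)
    pools = {
        g: targets[i * pool_size : (i + 1) * pool_size] for i, g in enumerate(groups)
    }
    bg_pool = targets[n_groups * pool_size :]

    records: list[InteractionRecord] = []
    n_pass = 0
    for comp in compounds:
        g = herb_groups.get(comp.herb_id)
        if g is None:
            raise ValueError(f"herb {comp.herb_id!r} missing from herb_groups")
        hit_in = np.asarray(pools[g])[rng.random(len(pools[g])) < p_within_group_target]
        hit_bg = np.asarray(bg_pool)[rng.random(len(bg_pool)) < p_background_target]
        for t in hit_in:
            records.append(
                InteractionRecord(comp.compound_id, str(t), confidence_high)
            )
            n_pass += confidence_high > 0.7
        for t in hit_bg:
            records.append(
                InteractionRecord(comp.compound_id, str(t), confidence_low)
            )
            n_pass += confidence_low > 0.7
    truth = SyntheticTruth(
        kind="interactions",
        seed=seed,
        params={
            "n_targets": n_targets,
            "p_within_group_target": p_within_group_target,
            "p_background_target": p_background_target,
            "confidence_high": confidence_high,
            "confidence_low": confidence_low,
        },
        data={
            "herb_groups": dict(sorted(herb_groups.items())),
            "group_pools": {str(g): pools[g] for g in groups},
            "background_pool": bg_pool,
            "n_interactions": len(records),
            "n_passing_confidence_07": int(n_pass),
        },
    )
    return records, truth


# ---------------------------------------------------------------------------
# Disease genes


def generate_disease_genes(
    universe: list[str],
    n_direct: int = 30,
    n_scored: int = 30,
    overlap: int = 15,
    gda_distribution=None,
    seed: int = 0,
) -> tuple[list[DiseaseGeneRecord], SyntheticTruth]:
    """Two-source disease-gene table with a planted intersection.

    `gda_distribution(rng, size)` draws the association scores for the scored
    source (default Uniform(0,1), which straddles the 0.3 cutoff).  The truth
    records the post-filter (score > 0.3) intersection and union.
    """
    if overlap > min(n_direct, n_scored):
        raise ValueError("overlap exceeds a source size")
    if n_direct + n_scored - overlap > len(universe):
        raise ValueError("universe too small")
    rng = _rng(seed, "disease_genes")
    chosen = list(rng.choice(universe, size=n_direct + n_scored - overlap, replace=False))
    direct = chosen[:n_direct]
    scored = chosen[n_direct - overlap : n_direct - overlap + n_scored]
    if gda_distribution is None:
        gda_distribution = lambda r, size: r.uniform(0.0, 1.0, size=size)
    scores = np.asarray(gda_distribution(rng, len(scored)), dtype=float)
    records = [
        DiseaseGeneRecord(gene=g, source=GeneSource.direct_evidence) for g in direct
    ] + [
        DiseaseGeneRecord(gene=g, source=GeneSource.scored, gda_score=float(s))
        for g, s in zip(scored, scores)
    ]
    passing = {g for g, s in zip(scored, scores) if s > 0.3}
    truth = SyntheticTruth(
        kind="disease_genes",
        seed=seed,
        params={"n_direct": n_direct, "n_scored": n_scored, "overlap": overlap},
        data={
            "direct": sorted(direct),
            "scored_passing": sorted(passing),
            "intersection": sorted(set(direct) & passing),
            "union": sorted(set(direct) | passing),
        },
    )
    return records, truth


# ---------------------------------------------------------------------------
# Gene-set library


def generate_geneset_library(
    background_size: int = 1000,
    n_terms: int = 50,
    term_size: tuple[int, int] = (40, 120),
    planted_terms: int = 3,
    query_size: int = 80,
    enrichment_strength: float = 0.5,
    seed: int = 0,
    universe: list[str] | None = None,
    term_prefix: str = "TERM",
) -> tuple[GeneSetLibrary, frozenset[str], SyntheticTruth]:
    """Gene-set library with terms planted to overlap a query.

    Planted terms share ``round(enrichment_strength * query_size)`` genes
    with the query; the remaining terms are uniform draws from the
    background, overlapping the query only by chance.
    """
    if not 0.0 < enrichment_strength <= 1.0:
        raise ValueError("enrichment_strength must lie in (0, 1]")
    if planted_terms > n_terms:
        raise ValueError("planted_terms exceeds n_terms")
    rng = _rng(seed, "library")
    background = universe if universe is not None else [
        _gene_id(i) for i in range(1, background_size + 1)
    ]
    background = list(background)
    query = list(rng.choice(background, size=query_size, replace=False))
    non_query = [g for g in background if g not in set(query)]
    lo, hi = term_size
    n_shared = max(1, round(enrichment_strength * query_size))
    sets: dict[str, frozenset[str]] = {}
    planted_names = []
    for i in range(1, n_terms + 1):
        name = f"{term_prefix}{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        if i <= planted_terms:
            shared = list(rng.choice(query, size=min(n_shared, size), replace=False))
            fill = list(
                rng.choice(non_query, size=max(size - len(shared), 0), replace=False)
            )
            sets[name] = frozenset(shared + fill)
            planted_names.append(name)
        else:
            sets[name] = frozenset(rng.choice(background, size=size, replace=False))
    library = GeneSetLibrary(sets, background=frozenset(background))
    truth = SyntheticTruth(
        kind="geneset_library",
        seed=seed,
        params={
            "background_size": len(background),
            "n_terms": n_terms,
            "term_size": list(term_size),
            "planted_terms": planted_terms,
            "query_size": query_size,
            "enrichment_strength": enrichment_strength,
        },
        data={"planted_terms": planted_names, "query": sorted(query)},
    )
    return library, frozenset(query), truth


# ---------------------------------------------------------------------------
# PPI stochastic block model


def generate_ppi_sbm(
    n_nodes: int = 60,
    n_blocks: int = 3,
    p_in: float = 0.5,
    p_out: float = 0.02,
    seed: int = 0,
    block_assignment: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Assortative stochastic block model over gene-symbol nodes.

    Blocks are equal slices of the node list unless an explicit
    `block_assignment` (node -> block id) is supplied.  Within-block pairs
    get an edge with probability `p_in`, between-block pairs with `p_out`.
    Returns an edge table (protein_a, protein_b) plus the planted labels.
    """
    if p_in <= p_out:
        raise ValueError("blocks not detectable by assortative modularity (p_in <= p_out)")
    rng = _rng(seed, "ppi")
    if block_assignment is None:
        nodes = [_gene_id(i) for i in range(1, n_nodes + 1)]
        per = n_nodes // n_blocks
        block_assignment = {
            node: min(i // per, n_blocks - 1) for i, node in enumerate(nodes)
        }
    else:
        nodes = sorted(block_assignment)
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            p = p_in if block_assignment[nodes[i]] == block_assignment[nodes[j]] else p_out
            if rng.random() < p:
                edges.append((nodes[i], nodes[j]))
    df = pd.DataFrame(edges, columns=["protein_a", "protein_b"])
    truth = SyntheticTruth(
        kind="ppi_sbm",
        seed=seed,
        params={"n_nodes": len(nodes), "p_in": p_in, "p_out": p_out},
        data={
            "blocks": dict(sorted(block_assignment.items())),
            "n_edges": len(edges),
        },
    )
    return df, truth


# ---------------------------------------------------------------------------
# Full demo dataset


def generate_all(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Materialize a coherent demo dataset (all pipeline inputs + truth files).

    The planted specific herbs of the corpus get compound tables; the herbs
    are split into three planted groups sharing target pools; disease genes
    are drawn from the target universe; the gene-set library plants three
    enriched terms per group pool; the PPI graph is an SBM whose blocks are
    the group pools plus the shared background pool.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    corpus, corpus_truth = generate_prescription_corpus(seed=seed)
    rows = [
        {"prescription_id": pid, "herb_id": herb}
        for pid, herbs in sorted(corpus.prescriptions.items())
        for herb, count in sorted(herbs.items())
        for _ in range(count)
    ]
    paths["corpus"] = out / "corpus.tsv"
    pd.DataFrame(rows).to_csv(paths["corpus"], sep="\t", index=False)
    paths["representative"] = out / "representative.txt"
    paths["representative"].write_text("\n".join(corpus.representative_ids) + "\n")
    corpus_truth.to_json(out / "truth_corpus.json")

    specific = corpus_truth.data["planted_specific_herbs"]
    compounds, compound_truth = generate_compound_tables(specific, seed=seed)
    paths["herb_compound"] = out / "herb_compound.tsv"
    pd.DataFrame(
        [
            {"herb_id": c.herb_id, "compound_id": c.compound_id, "qed": c.qed}
            for c in compounds
        ]
    ).to_csv(paths["herb_compound"], sep="\t", index=False, float_format="%.10g")
    compound_truth.to_json(out / "truth_compounds.json")

    # three planted herb groups over the specific herbs (sizes 4/3/3)
    herb_groups = {h: (0 if i < 4 else 1 if i < 7 else 2) for i, h in enumerate(specific)}
    interactions, interaction_truth = generate_interactions(
        compounds, herb_groups=herb_groups, seed=seed
    )
    paths["compound_target"] = out / "compound_target.tsv"
    pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "target_gene": r.target_gene,
                "confidence": r.confidence,
            }
            for r in interactions
        ]
    ).to_csv(paths["compound_target"], sep="\t", index=False, float_format="%.10g")
    interaction_truth.to_json(out / "truth_interactions.json")

    universe = [_gene_id(i) for i in range(1, interaction_truth.params["n_targets"] + 1)]
    disease, disease_truth = generate_disease_genes(universe, seed=seed)
    paths["disease_genes"] = out / "disease_genes.tsv"
    pd.DataFrame(
        [
            {
                "gene": r.gene,
                "source": r.source.value,
                "gda_score": "" if r.gda_score is None else f"{r.gda_score:.10g}",
            }
            for r in disease
        ]
    ).to_csv(paths["disease_genes"], sep="\t", index=False)
    disease_truth.to_json(out / "truth_disease_genes.json")

    # gene-set libraries over the target universe: three planted terms per group pool
    pools = interaction_truth.data["group_pools"]
    sets: dict[str, frozenset[str]] = {}
    planted_by_group: dict[str, list[str]] = {}
    lib_rng = _rng(seed, "library")
    for g, pool in sorted(pools.items()):
        names = []
        for t in range(1, 4):
            name = f"GRP{g}_TERM{t:02d}"
            core = list(lib_rng.choice(pool, size=max(3, int(0.7 * len(pool))), replace=False))
            fill = list(lib_rng.choice(universe, size=10, replace=False))
            sets[name] = frozenset(core) | frozenset(fill)
            names.append(name)
        planted_by_group[g] = names
    for t in range(1, 31):
        size = int(lib_rng.integers(20, 60))
        sets[f"BGTERM{t:04d}"] = frozenset(lib_rng.choice(universe, size=size, replace=False))
    library = GeneSetLibrary(sets, background=frozenset(universe))
    paths["go_bp"] = out / "go_bp.gmt"
    write_gmt(library, paths["go_bp"])
    paths["pathways"] = out / "pathways.gmt"
    write_gmt(library, paths["pathways"])
    SyntheticTruth(
        kind="geneset_library",
        seed=seed,
        params={"n_terms": len(sets)},
        data={"planted_terms_by_group": planted_by_group},
    ).to_json(out / "truth_library.json")

    blocks = {}
    for g, pool in sorted(pools.items()):
        for node in pool:
            blocks[node] = int(g) + 1
    for node in interaction_truth.data["background_pool"]:
        blocks[node] = 0
    ppi_edges, ppi_truth = generate_ppi_sbm(
        p_in=0.5, p_out=0.02, seed=seed, block_assignment=blocks
    )
    paths["ppi_edges"] = out / "ppi_edges.tsv"
    ppi_edges.to_csv(paths["ppi_edges"], sep="\t", index=False)
    ppi_truth.to_json(out / "truth_ppi.json")

    return paths
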