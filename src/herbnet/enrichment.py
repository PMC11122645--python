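"""Over-representation analysis of gene lists against gene-set libraries.

The test is the one-sided upper-tail hypergeometric (Fisher's exact) test,
adjusted across a library with Benjamini-Hochberg.  On top of the p-value,
each term gets a rank-deviation z-score — how far the term's p-value rank for
the observed query sits from its expected rank under random queries of the
same size — and the two are fused into a combined score

    c = ln(p) * z

which is positive for enriched terms (small p, negative z).  An herb-level
combined score sums the combined scores of the herb's compounds whose
adjusted p-value is below 0.05.

The z-score null is a seeded permutation null: ``n_null`` random queries of
the observed size are drawn uniformly from the background, every library term
is ranked by p-value for each, and the per-term rank mean and standard
deviation define the reference.  This mirrors the rank-deviation statistic of
standard enrichment web tools, which precompute the same quantity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetLibrary",
    "EnrichmentResult",
    "HerbCombinedScore",
    "fisher_enrichment",
    "bh_adjust",
    "rank_z_score",
    "combined_score",
    "herb_combined_score",
    "enrich_library",
    "read_gmt",
    "write_gmt",
]

_P_FLOOR = 1e-300  # smallest p passed to ln(); hypergeom.sf can underflow to 0


class GeneSetLibrary:
    """Named gene sets over a background universe.

    If `background` is omitted it defaults to the union of all set members.
    Genes outside the background are dropped (count logged); sets emptied by
    harmonization are removed with a warning.
    """

    def __init__(
        self,
        sets: dict[str, set[str] | frozenset[str]],
        background: set[str] | frozenset[str] | None = None,
    ) -> None:
        if background is None:
            background = frozenset().union(*map(frozenset, sets.values())) if sets else frozenset()
        self.background: frozenset[str] = frozenset(background)
        dropped_genes = 0
        harmonized: dict[str, frozenset[str]] = {}
        for term, genes in sets.items():
            genes = frozenset(genes)
            inside = genes & self.background
            dropped_genes += len(genes) - len(inside)
            if not inside:
                logger.warning("gene set %r empty after harmonization; removed", term)
                continue
            harmonized[term] = inside
        if dropped_genes:
            logger.info("dropped %d gene-set members outside the background", dropped_genes)
        self.sets: dict[str, frozenset[str]] = harmonized

    @property
    def terms(self) -> list[str]:
        return sorted(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    overlap_k: int
    set_size_K: int
    p: float
    adj_p: float
    z: float
    combined: float


@dataclass(frozen=True)
class HerbCombinedScore:
    herb_id: str
    term: str
    score: float


# ---------------------------------------------------------------------------
# Core statistics


def fisher_enrichment(
    query: set[str] | frozenset[str],
    gene_set: set[str] | frozenset[str],
    background: set[str] | frozenset[str],
) -> float:
    """Upper-tail hypergeometric probability P(X >= k) of the observed overlap.

    N = |background|, K = |gene_set|, n = |query|, k = |query & gene_set|.
    """
    background = frozenset(background)
    if not background:
        raise ValueError("background is empty")
    query = frozenset(query)
    outside = query - background
    if outside:
        raise ValueError(f"query genes outside background: {sorted(outside)}")
    gene_set = frozenset(gene_set) & background
    N, K, n = len(background), len(gene_set), len(query)
    k = len(query & gene_set)
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def combined_score(p: float, z: float) -> float:
    """c = ln(p) * z; positive for enriched terms (p < 1 and z < 0)."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    return math.log(p) * z


def herb_combined_score(
    per_compound_results: dict[str, EnrichmentResult],
    herb_id: str,
    term: str,
    alpha: float = 0.05,
) -> HerbCombinedScore:
    """Sum of combined scores over compounds with adjusted p strictly below alpha."""
    total = sum(
        r.combined for r in per_compound_results.values() if r.adj_p < alpha
    )
    return HerbCombinedScore(herb_id=herb_id, term=term, score=total)


# ---------------------------------------------------------------------------
# Library-level machinery

class _LibraryMatrix:
    """Boolean term-by-gene membership matrix for vectorized overlap counting."""

    def __init__(self, library: GeneSetLibrary) -> None:
        self.terms = library.terms
        self.genes = sorted(library.background)
        gene_index = {g: i for i, g in enumerate(self.genes)}
        self.M = np.zeros((len(self.terms), len(self.genes)), dtype=bool)
        for t, term in enumerate(self.terms):
            for g in library.sets[term]:
                self.M[t, gene_index[g]] = True
        self.K = self.M.sum(axis=1)
        self.gene_index = gene_index

    def overlaps(self, query_idx: np.ndarray) -> np.ndarray:
        return self.M[:, query_idx].sum(axis=1)

    def pvalues(self, query_idx: np.ndarray) -> np.ndarray:
        k = self.overlaps(query_idx)
        N, n = len(self.genes), len(query_idx)
        return hypergeom.sf(k - 1, N, self.K, n)


def _ranks(p: np.ndarray) -> np.ndarray:
    """1-based rank of each term when sorted by (p, term order); deterministic."""
    order = np.lexsort((np.arange(len(p)), p))
    ranks = np.empty(len(p), dtype=float)
    ranks[order] = np.arange(1, len(p) + 1)
    return ranks


def _null_rank_stats(
    matrix: _LibraryMatrix, query_size: int, n_null: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-term mean and sd of p-value ranks over random same-size queries.

    Fully vectorized: all null queries are drawn at once and the term ranks
    are computed column-wise with a stable sort, so ties break on term order
    exactly as in :func:`_ranks`.
    """
    rng = np.random.default_rng(seed)
    n_genes = len(matrix.genes)
    n_terms = len(matrix.terms)
    # uniform queries without replacement: first `query_size` of a random order
    idx = np.argsort(rng.random((n_null, n_genes)), axis=1)[:, :query_size]
    overlaps = matrix.M[:, idx].sum(axis=2)  # terms x n_null
    p = hypergeom.sf(overlaps - 1, n_genes, matrix.K[:, None], query_size)
    order = np.argsort(p, axis=0, kind="stable")
    ranks = np.empty_like(p)
    np.put_along_axis(
        ranks, order, np.broadcast_to(np.arange(1.0, n_terms + 1)[:, None], p.shape), axis=0
    )
    return ranks.mean(axis=1), ranks.std(axis=1)


def rank_z_score(
    query: set[str] | frozenset[str],
    term: str,
    library: GeneSetLibrary,
    n_null: int = 500,
    seed: int = 0,
) -> float:
    """Deviation of a term's observed p-value rank from its permutation-null rank.

    z = (observed_rank - mean_null_rank) / sd_null_rank; enriched terms rank
    earlier than expected and get negative z.
    """
    if n_null < 100:
        raise ValueError("n_null must be at least 100")
    if term not in library.sets:
        raise KeyError(f"unknown term: {term!r}")
    matrix = _LibraryMatrix(library)
    query_idx = _query_indices(query, matrix)
    obs = _ranks(matrix.pvalues(query_idx))
    mean, sd = _null_rank_stats(matrix, len(query_idx), n_null, seed)
    t = matrix.terms.index(term)
    if sd[t] == 0:
        logger.warning("null rank sd is 0 for term %r; z set to 0", term)
        return 0.0
    return float((obs[t] - mean[t]) / sd[t])


def _query_indices(query, matrix: _LibraryMatrix) -> np.ndarray:
    query = frozenset(query)
    outside = query - set(matrix.gene_index)
    if outside:
        raise ValueError(f"query genes outside background: {sorted(outside)}")
    return np.asarray(sorted(matrix.gene_index[g] for g in query), dtype=int)


def enrich_library(
    query: set[str] | frozenset[str],
    library: GeneSetLibrary,
    seed: int = 0,
    n_null: int = 500,
    _matrix: "_LibraryMatrix | None" = None,
    _null_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[EnrichmentResult]:
    """Score every library term for a query gene list.

    Results carry p, BH-adjusted p across the library, the rank-deviation z
    and the combined score, sorted by adjusted p ascending with ties broken
    by combined score descending then term name.  Top-k reporting is a slice
    of this list, not a re-computation.
    """
    if not query:
        raise ValueError("empty query")
    matrix = _matrix if _matrix is not None else _LibraryMatrix(library)
    query_idx = _query_indices(query, matrix)
    p = np.maximum(matrix.pvalues(query_idx), _P_FLOOR)
    adj = np.asarray(bh_adjust(p.tolist()))
    obs_rank = _ranks(p)
    if _null_stats is not None:
        mean, sd = _null_stats
    else:
        mean, sd = _null_rank_stats(matrix, len(query_idx), n_null, seed)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs_rank - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    k = matrix.overlaps(query_idx)
    results = [
        EnrichmentResult(
            term=matrix.terms[t],
            overlap_k=int(k[t]),
            set_size_K=int(matrix.K[t]),
            p=float(p[t]),
            adj_p=float(adj[t]),
            z=float(z[t]),
            combined=math.log(p[t]) * float(z[t]),
        )
        for t in range(len(matrix.terms))
    ]
    results.sort(key=lambda r: (r.adj_p, -r.combined, r.term))
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "overlap": f"{r.overlap_k}/{r.set_size_K}",
                "p": r.p,
                "adj_p": r.adj_p,
                "z": r.z,
                "combined": r.combined,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path: str, background: set[str] | None = None) -> GeneSetLibrary:
    """Read a GMT file (term, description, member genes; tab-separated)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            term, _desc, *genes = fields
            sets[term] = frozenset(g for g in genes if g)
    return GeneSetLibrary(sets, background=background)


def write_gmt(library: GeneSetLibrary, path: str, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term in library.terms:
            genes = "\t".join(sorted(library.sets[term]))
            fh.write(f"{term}\t{description}\t{genes}\n")
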