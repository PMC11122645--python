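"""PPI network module detection and functional profiling.

The protein-protein interaction graph is induced on the predicted target
proteins, cleaned of self-loops and duplicate edges, and partitioned into
modules with the Louvain method (greedy modularity optimization with
recursive community condensation).  Herb-group target sets are projected
onto the modules, and each module is profiled with gene-set
over-representation analysis (top-10 terms by adjusted p).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .enrichment import EnrichmentResult, GeneSetLibrary, _LibraryMatrix, _null_rank_stats, enrich_library

logger = logging.getLogger(__name__)

__all__ = [
    "PPIGraph",
    "ModulePartition",
    "GroupProjection",
    "build_ppi",
    "modularity",
    "louvain_partition",
    "project_group",
    "module_go_profile",
]


@dataclass
class PPIGraph:
    """Undirected simple PPI graph plus bookkeeping from its construction."""

    graph: nx.Graph
    isolates: frozenset[str]
    n_self_loops_dropped: int = 0
    n_duplicates_dropped: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ModulePartition:
    assignment: dict[str, int]  # node -> module id (1-based, by descending size)
    modularity: float
    seed: int | None = None
    resolution: float = 1.0

    @property
    def module_sizes(self) -> dict[int, int]:
        return dict(sorted(Counter(self.assignment.values()).items()))

    @property
    def coverage(self) -> dict[int, float]:
        n = len(self.assignment)
        return {m: s / n for m, s in self.module_sizes.items()}

    def members(self, module: int) -> frozenset[str]:
        return frozenset(n for n, m in self.assignment.items() if m == module)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["gene", "module"]
        )


@dataclass
class GroupProjection:
    group_id: str
    n_nodes: int
    n_edges: int
    module_counts: dict[int, int]
    included_modules: tuple[int, ...] = field(default_factory=tuple)


def build_ppi(edges: pd.DataFrame, targets: set[str] | frozenset[str]) -> PPIGraph:
    """Induce a simple undirected PPI graph on `targets`.

    Self-loops and duplicate edges are dropped (counts logged); targets with
    no surviving interaction are kept as isolated nodes and reported.
    """
    if len(edges) == 0:
        raise ValueError("empty edge table")
    targets = frozenset(targets)
    g = nx.Graph()
    g.add_nodes_from(sorted(targets))
    self_loops = duplicates = 0
    cols = list(edges.columns)
    for a, b in zip(edges[cols[0]], edges[cols[1]]):
        a, b = str(a), str(b)
        if a not in targets or b not in targets:
            continue
        if a == b:
            self_loops += 1
            continue
        if g.has_edge(a, b):
            duplicates += 1
            continue
        g.add_edge(a, b)
    isolates = frozenset(nx.isolates(g))
    if self_loops or duplicates:
        logger.info(
            "PPI cleanup: dropped %d self-loops, %d duplicate edges", self_loops, duplicates
        )
    if isolates:
        logger.info("PPI graph has %d isolated targets", len(isolates))
    return PPIGraph(
        graph=g,
        isolates=isolates,
        n_self_loops_dropped=self_loops,
        n_duplicates_dropped=duplicates,
    )


def modularity(graph: PPIGraph | nx.Graph, assignment: dict[str, int]) -> float:
    """Newman-Girvan modularity Q = sum_c [ e_c/m - (d_c / 2m)^2 ].

    e_c counts intra-module edges, d_c the total degree of module c, m the
    edge count.  Computed directly from the definition.
    """
    g = graph.graph if isinstance(graph, PPIGraph) else graph
    missing = [n for n in g.nodes if n not in assignment]
    if missing:
        raise ValueError(f"nodes missing from partition: {sorted(missing)[:5]}")
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    intra: Counter = Counter()
    degree: Counter = Counter()
    for u, v in g.edges:
        if assignment[u] == assignment[v]:
            intra[assignment[u]] += 1
        degree[assignment[u]] += 1
        degree[assignment[v]] += 1
    modules = set(assignment[n] for n in g.nodes)
    return float(
        sum(intra[c] / m - (degree[c] / (2 * m)) ** 2 for c in modules)
    )


def louvain_partition(
    graph: PPIGraph | nx.Graph,
    seed: int,
    resolution: float = 1.0,
    weighted: bool = False,
) -> ModulePartition:
    """Louvain community detection; module ids relabeled by descending size.

    Size ties break on the smallest member node.  The result is guaranteed
    not to score below the trivial one-module and all-singletons partitions.
    """
    g = graph.graph if isinstance(graph, PPIGraph) else graph
    if g.number_of_edges() == 0:
        raise ValueError("edgeless graph: no modules to detect")
    weight = "weight" if weighted else None
    communities = nx.community.louvain_communities(
        g, seed=seed, resolution=resolution, weight=weight
    )
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    assignment = {n: i for i, comm in enumerate(ordered, start=1) for n in comm}
    q = modularity(g, assignment)
    one_module = modularity(g, {n: 0 for n in g.nodes})
    singletons = modularity(g, {n: i for i, n in enumerate(g.nodes)})
    baseline = max(one_module, singletons)
    if q < baseline:  # pathological; fall back to the better trivial partition
        logger.warning("Louvain Q=%.4f below trivial baseline %.4f; using baseline", q, baseline)
        if one_module >= singletons:
            assignment = {n: 1 for n in g.nodes}
        else:
            assignment = {n: i for i, n in enumerate(sorted(g.nodes), start=1)}
        q = baseline
    return ModulePartition(
        assignment=assignment, modularity=q, seed=seed, resolution=resolution
    )


def project_group(
    graph: PPIGraph | nx.Graph,
    partition: ModulePartition,
    group_targets: set[str] | frozenset[str],
    group_id: str = "group",
    module_floor: float = 0.05,
) -> GroupProjection:
    """Project a herb group's target set onto the module partition.

    Reports the induced subgraph size and per-module membership counts; a
    module is "included" when the group's members exceed `module_floor` of
    the module's size (strictly).
    """
    g = graph.graph if isinstance(graph, PPIGraph) else graph
    present = frozenset(group_targets) & set(g.nodes)
    if not present:
        logger.warning("group %r has no targets in the PPI graph", group_id)
        return GroupProjection(group_id=group_id, n_nodes=0, n_edges=0, module_counts={})
    sub = g.subgraph(present)
    counts = Counter(partition.assignment[n] for n in present)
    sizes = partition.module_sizes
    included = tuple(
        sorted(m for m, c in counts.items() if c / sizes[m] > module_floor)
    )
    return GroupProjection(
        group_id=group_id,
        n_nodes=sub.number_of_nodes(),
        n_edges=sub.number_of_edges(),
        module_counts=dict(sorted(counts.items())),
        included_modules=included,
    )


def module_go_profile(
    partition: ModulePartition,
    library: GeneSetLibrary,
    seed: int,
    top_k: int = 10,
    n_null: int = 500,
    min_module_size: int = 3,
    extra_queries: dict[str, frozenset[str]] | None = None,
) -> dict[str, list[EnrichmentResult]]:
    """Top-k enrichment terms per module (and per optional extra query set).

    Modules smaller than `min_module_size` genes are skipped with a warning.
    Genes absent from the library background are ignored for querying.
    """
    matrix = _LibraryMatrix(library)
    queries: dict[str, frozenset[str]] = {
        f"module_{m}": partition.members(m) for m in partition.module_sizes
    }
    if extra_queries:
        queries.update(extra_queries)
    null_cache: dict[int, tuple] = {}
    profiles: dict[str, list[EnrichmentResult]] = {}
    for name, genes in queries.items():
        usable = frozenset(genes) & library.background
        if len(usable) < min_module_size:
            logger.warning("query %r has %d usable genes (< %d); skipped", name, len(usable), min_module_size)
            continue
        size = len(usable)
        if size not in null_cache:
            null_cache[size] = _null_rank_stats(matrix, size, n_null, seed)
        results = enrich_library(
            usable, library, seed=seed, n_null=n_null,
            _matrix=matrix, _null_stats=null_cache[size],
        )
        profiles[name] = results[:top_k]
    return profiles
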