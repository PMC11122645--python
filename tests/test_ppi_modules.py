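"""PPI graph construction, modularity, Louvain modules, group projection."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from herbnet import (
    GeneSetLibrary,
    build_ppi,
    generate_geneset_library,
    generate_ppi_sbm,
    louvain_partition,
    modularity,
    module_go_profile,
    project_group,
)


def edges_df(pairs):
    return pd.DataFrame(pairs, columns=["protein_a", "protein_b"])


def brute_force_modularity(g: nx.Graph, assignment: dict) -> float:
    """Edge-by-edge oracle: Q = sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j) / 2m."""
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    nodes = list(g.nodes)
    A = nx.to_numpy_array(g, nodelist=nodes)
    k = A.sum(axis=1)
    q = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if assignment[u] == assignment[v]:
                q += A[i, j] - k[i] * k[j] / (2 * m)
    return q / (2 * m)


def all_partitions(items):
    """Every partition of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def two_triangles(bridge: bool) -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
    g.add_edges_from([("x", "y"), ("y", "z"), ("x", "z")])
    if bridge:
        g.add_edge("c", "x")
    return g


class TestBuildPPI:
    def test_dedup_and_self_loop_removal(self):
        graph = build_ppi(edges_df([("a", "b"), ("b", "a"), ("a", "a")]), {"a", "b"})
        assert graph.n_nodes == 2 and graph.n_edges == 1
        assert graph.n_self_loops_dropped == 1
        assert graph.n_duplicates_dropped == 1

    def test_isolated_target_reported(self):
        graph = build_ppi(edges_df([("a", "b")]), {"a", "b", "c"})
        assert graph.isolates == {"c"}
        assert graph.n_nodes == 3

    def test_off_target_edges_excluded(self):
        graph = build_ppi(edges_df([("a", "b"), ("a", "q")]), {"a", "b"})
        assert graph.n_edges == 1

    def test_empty_edge_table_rejected(self):
        with pytest.raises(ValueError, match="empty edge table"):
            build_ppi(edges_df([]), {"a"})

    def test_sbm_bookkeeping(self):
        edges, truth = generate_ppi_sbm(n_nodes=40, n_blocks=2, seed=13)
        graph = build_ppi(edges, set(truth.data["blocks"]))
        assert graph.n_nodes == 40
        assert graph.n_edges == truth.data["n_edges"]


class TestModularity:
    def test_single_module_is_zero(self):
        g = two_triangles(bridge=True)
        assert modularity(g, {n: 0 for n in g.nodes}) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles_by_component(self):
        g = two_triangles(bridge=False)
        part = {n: (0 if n in "abc" else 1) for n in g.nodes}
        assert modularity(g, part) == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_on_random_small_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            part = {v: int(rng.integers(3)) for v in g.nodes}
            assert modularity(g, part) == pytest.approx(
                brute_force_modularity(g, part), abs=1e-12
            )
            assert modularity(g, part) == pytest.approx(
                nx.community.modularity(
                    g, [{v for v in g if part[v] == c} for c in set(part.values())]
                ),
                abs=1e-12,
            )

    def test_missing_node_rejected(self):
        g = two_triangles(bridge=False)
        with pytest.raises(ValueError, match="missing"):
            modularity(g, {"a": 0})


class TestLouvain:
    def test_bridged_triangles_match_exhaustive_optimum(self):
        g = two_triangles(bridge=True)
        best_q, best_part = -1.0, None
        for partition in all_partitions(list(g.nodes)):
            assign = {n: i for i, block in enumerate(partition) for n in block}
            q = modularity(g, assign)
            if q > best_q:
                best_q, best_part = q, assign
        found = louvain_partition(g, seed=0)
        assert found.modularity == pytest.approx(best_q, abs=1e-12)
        assert adjusted_rand_score(
            [best_part[n] for n in g.nodes], [found.assignment[n] for n in g.nodes]
        ) == 1.0

    def test_no_module_spans_components(self):
        g = two_triangles(bridge=False)
        part = louvain_partition(g, seed=1)
        for comp in nx.connected_components(g):
            modules = {part.assignment[n] for n in comp}
            for other in nx.connected_components(g):
                if comp != other:
                    assert modules.isdisjoint(part.assignment[n] for n in other)

    def test_planted_sbm_recovered(self):
        edges, truth = generate_ppi_sbm(n_nodes=60, n_blocks=3, p_in=0.5, p_out=0.02, seed=13)
        blocks = truth.data["blocks"]
        graph = build_ppi(edges, set(blocks))
        part = louvain_partition(graph, seed=13)
        nodes = sorted(blocks)
        assert adjusted_rand_score(
            [blocks[n] for n in nodes], [part.assignment[n] for n in nodes]
        ) == 1.0

    def test_q_not_below_trivial_baselines(self):
        edges, truth = generate_ppi_sbm(n_nodes=30, n_blocks=2, seed=3)
        graph = build_ppi(edges, set(truth.data["blocks"]))
        part = louvain_partition(graph, seed=3)
        g = graph.graph
        assert part.modularity >= modularity(g, {n: 0 for n in g.nodes}) - 1e-12
        assert part.modularity >= modularity(g, {n: i for i, n in enumerate(g.nodes)}) - 1e-12

    def test_stored_q_matches_recomputation(self):
        edges, truth = generate_ppi_sbm(n_nodes=30, n_blocks=3, seed=5)
        graph = build_ppi(edges, set(truth.data["blocks"]))
        part = louvain_partition(graph, seed=5)
        assert part.modularity == pytest.approx(
            modularity(graph, part.assignment), abs=1e-9
        )

    def test_deterministic_given_seed(self):
        edges, truth = generate_ppi_sbm(n_nodes=50, n_blocks=3, seed=7)
        graph = build_ppi(edges, set(truth.data["blocks"]))
        assert louvain_partition(graph, seed=9).assignment == louvain_partition(
            graph, seed=9
        ).assignment

    def test_module_ids_by_descending_size(self):
        edges, truth = generate_ppi_sbm(n_nodes=40, n_blocks=2, seed=2)
        graph = build_ppi(edges, set(truth.data["blocks"]))
        sizes = louvain_partition(graph, seed=2).module_sizes
        assert list(sizes.values()) == sorted(sizes.values(), reverse=True)

    def test_edgeless_graph_rejected(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(ValueError, match="edgeless"):
            louvain_partition(g, seed=0)


class TestGroupProjection:
    @pytest.fixture
    def sbm(self):
        edges, truth = generate_ppi_sbm(n_nodes=60, n_blocks=3, p_in=0.5, p_out=0.02, seed=13)
        blocks = truth.data["blocks"]
        graph = build_ppi(edges, set(blocks))
        part = louvain_partition(graph, seed=13)
        return graph, part, blocks

    def test_whole_graph_group_counts_equal_module_sizes(self, sbm):
        graph, part, _ = sbm
        proj = project_group(graph, part, set(graph.graph.nodes), group_id="all")
        assert proj.module_counts == part.module_sizes

    def test_block_confined_group_includes_single_module(self, sbm):
        graph, part, blocks = sbm
        block0 = {n for n, b in blocks.items() if b == 0}
        proj = project_group(graph, part, block0, group_id="g0")
        assert len(proj.included_modules) == 1

    def test_additive_over_disjoint_groups(self, sbm):
        graph, part, blocks = sbm
        g1 = {n for n, b in blocks.items() if b == 0}
        g2 = {n for n, b in blocks.items() if b == 1}
        p1 = project_group(graph, part, g1)
        p2 = project_group(graph, part, g2)
        both = project_group(graph, part, g1 | g2)
        for m in both.module_counts:
            assert both.module_counts[m] == p1.module_counts.get(m, 0) + p2.module_counts.get(m, 0)

    def test_disjoint_group_warns_and_empties(self, sbm, caplog):
        graph, part, _ = sbm
        with caplog.at_level("WARNING"):
            proj = project_group(graph, part, {"NOT_A_GENE"}, group_id="ghost")
        assert proj.n_nodes == 0 and proj.module_counts == {}


class TestModuleProfile:
    def test_module_equal_to_term_ranks_first(self, sbm_library=None):
        edges, truth = generate_ppi_sbm(n_nodes=30, n_blocks=2, p_in=0.8, p_out=0.02, seed=21)
        blocks = truth.data["blocks"]
        graph = build_ppi(edges, set(blocks))
        part = louvain_partition(graph, seed=21)
        module1 = part.members(1)
        universe = sorted(graph.graph.nodes)
        sets = {"match": set(module1), "other": set(universe[:8])}
        library = GeneSetLibrary(sets, background=set(universe))
        profiles = module_go_profile(part, library, seed=0, n_null=100)
        assert profiles["module_1"][0].term == "match"

    def test_small_module_skipped(self, caplog):
        g = nx.Graph([("a", "b"), ("c", "d"), ("d", "e"), ("c", "e")])
        part = louvain_partition(g, seed=0)
        library = GeneSetLibrary({"t": {"a", "b", "c", "d", "e"}})
        with caplog.at_level("WARNING"):
            profiles = module_go_profile(part, library, seed=0, n_null=100)
        assert "module_2" not in profiles  # the 2-node module
        assert "skipped" in caplog.text

    def test_planted_library_terms_fill_top_ranks(self):
        library, query, truth = generate_geneset_library(
            background_size=400, n_terms=30, term_size=(20, 60),
            planted_terms=3, query_size=40, enrichment_strength=0.6, seed=5,
        )
        g = nx.Graph()
        genes = sorted(query)
        g.add_edges_from(zip(genes[:-1], genes[1:]))  # one module = the query
        part = louvain_partition(g, seed=0)
        part.assignment = {n: 1 for n in g.nodes}  # single module
        profiles = module_go_profile(part, library, seed=5, n_null=200)
        top = {r.term for r in profiles["module_1"][:3]}
        assert top == set(truth.data["planted_terms"])
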