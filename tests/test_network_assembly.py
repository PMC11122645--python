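"""Filtering cutoffs, tripartite assembly, disease-gene merge and overlap."""

import numpy as np
import pandas as pd
import pytest

from herbnet import (
    CompoundRecord,
    DiseaseGeneRecord,
    InteractionRecord,
    build_network,
    elbow_threshold,
    filter_confident,
    filter_druglike,
    generate_compound_tables,
    generate_interactions,
    merge_disease_genes,
    overlap_with_disease,
)


def C(cid, herb, qed):
    return CompoundRecord(compound_id=cid, herb_id=herb, qed=qed)


def I(cid, gene, conf):
    return InteractionRecord(compound_id=cid, target_gene=gene, confidence=conf)


class TestFilters:
    def test_qed_boundary_is_strict(self):
        records = [C("c1", "h", 0.34), C("c2", "h", 0.35), C("c3", "h", 0.36)]
        assert [c.compound_id for c in filter_druglike(records)] == ["c3"]

    def test_confidence_boundary_is_strict(self):
        records = [I("c", "g", 0.69), I("c", "g2", 0.70), I("c", "g3", 0.71)]
        assert [r.target_gene for r in filter_confident(records)] == ["g3"]

    def test_empty_inputs(self):
        assert filter_druglike([]) == []
        assert filter_confident([]) == []

    def test_uniform_confidences_match_direct_scan(self):
        rng = np.random.default_rng(7)
        confs = rng.uniform(0, 1, size=100)
        records = [I(f"c{i}", "g", float(c)) for i, c in enumerate(confs)]
        expected = int(np.sum(confs > 0.7))
        assert len(filter_confident(records)) == expected

    def test_filters_idempotent(self):
        rng = np.random.default_rng(3)
        comps = [C(f"c{i}", "h", float(q)) for i, q in enumerate(rng.uniform(0, 1, 50))]
        once = filter_druglike(comps)
        assert filter_druglike(once) == once

    @pytest.mark.parametrize("lo,hi", [(0.2, 0.5), (0.5, 0.9)])
    def test_raising_cutoff_never_retains_more(self, lo, hi):
        rng = np.random.default_rng(11)
        comps = [C(f"c{i}", "h", float(q)) for i, q in enumerate(rng.uniform(0, 1, 80))]
        assert len(filter_druglike(comps, cutoff=hi)) <= len(filter_druglike(comps, cutoff=lo))

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError, match="qed"):
            C("c", "h", 1.2)
        with pytest.raises(ValueError, match="confidence"):
            I("c", "g", -0.1)


class TestBuildNetwork:
    def test_edge_counts(self):
        comps = [C("c1", "h", 0.8), C("c2", "h", 0.8)]
        inter = [I("c1", "g1", 0.9), I("c1", "g2", 0.9), I("c2", "g3", 0.9)]
        net = build_network(comps, inter)
        counts = net.edge_counts().set_index("herb_id")
        assert counts.loc["h", "n_hc"] == 2
        assert counts.loc["h", "n_ct"] == 3

    def test_shared_compound_reachable_from_both_herbs(self):
        comps = [C("shared", "h1", 0.8), C("shared", "h2", 0.8)]
        inter = [I("shared", "g", 0.9)]
        net = build_network(comps, inter)
        assert net.compounds_of("h1") == net.compounds_of("h2") == frozenset({"shared"})
        assert net.targets_of("h1") == net.targets_of("h2") == frozenset({"g"})
        g = net.to_networkx()
        assert g.degree("compound::shared") == 3  # two herbs + one target

    def test_orphan_interactions_dropped_with_warning(self, caplog):
        comps = [C("c1", "h", 0.8)]
        inter = [I("c1", "g", 0.9), I("ghost", "g", 0.9)]
        with caplog.at_level("WARNING"):
            net = build_network(comps, inter)
        assert net.compound_target_edges == frozenset({("c1", "g")})
        assert "unknown compounds" in caplog.text

    def test_generator_bookkeeping(self):
        herbs = [f"hrb{i:04d}" for i in range(1, 5)]
        compounds, _ = generate_compound_tables(herbs, seed=3)
        interactions, truth = generate_interactions(
            compounds, herb_groups={h: 0 for h in herbs}, seed=3
        )
        assert len(interactions) == truth.data["n_interactions"]
        kept = filter_confident(interactions)
        assert len(kept) == truth.data["n_passing_confidence_07"]
        net = build_network(compounds, interactions)
        assert len(net.herb_compound_edges) == len(compounds)
        assert len(net.compound_target_edges) == len(
            {(r.compound_id, r.target_gene) for r in interactions}
        )


class TestDiseaseGeneMerge:
    RECORDS = [
        DiseaseGeneRecord("A", "direct_evidence"),
        DiseaseGeneRecord("B", "direct_evidence"),
        DiseaseGeneRecord("C", "direct_evidence"),
        DiseaseGeneRecord("B", "scored", 0.5),
        DiseaseGeneRecord("C", "scored", 0.8),
        DiseaseGeneRecord("D", "scored", 0.4),
    ]

    def test_intersection(self):
        assert merge_disease_genes(self.RECORDS, mode="intersection") == {"B", "C"}

    def test_union(self):
        assert merge_disease_genes(self.RECORDS, mode="union") == {"A", "B", "C", "D"}

    def test_gda_boundary_is_strict(self):
        records = self.RECORDS + [DiseaseGeneRecord("E", "scored", 0.3)]
        assert "E" not in merge_disease_genes(records, mode="union")

    def test_empty_result_warns_not_errors(self, caplog):
        records = [
            DiseaseGeneRecord("A", "direct_evidence"),
            DiseaseGeneRecord("B", "scored", 0.9),
        ]
        with caplog.at_level("WARNING"):
            out = merge_disease_genes(records, mode="intersection")
        assert out == frozenset()
        assert "empty" in caplog.text

    def test_scored_without_score_rejected(self):
        with pytest.raises(ValueError, match="gda_score"):
            DiseaseGeneRecord("X", "scored")


def _brute_force_elbow(vals):
    """Max perpendicular distance to the first-last chord, smallest index wins."""
    import math

    n = len(vals)
    x0, y0, x1, y1 = 0.0, vals[0], n - 1.0, vals[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = math.hypot(dx, dy)
    best_i, best_d = None, -1.0
    for i in range(1, n - 1):
        d = abs(dy * (i - x0) - dx * (vals[i] - y0)) / norm
        if d > best_d:
            best_i, best_d = i, d
    return vals[best_i]


class TestElbow:
    def test_knee_detection(self):
        vals = [1.0, 0.9, 0.8, 0.2, 0.1]
        assert elbow_threshold(vals) == 0.8
        assert elbow_threshold(vals) == _brute_force_elbow(vals)

    def test_step_function(self):
        vals = [1, 1, 1, 0, 0]
        assert elbow_threshold(vals) == _brute_force_elbow(vals) == 1.0

    def test_random_curves_match_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            vals = sorted(rng.uniform(0, 1, size=rng.integers(3, 30)), reverse=True)
            assert elbow_threshold(vals) == _brute_force_elbow(vals)

    def test_collinear_degenerates_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = elbow_threshold([1.0, 0.75, 0.5, 0.25, 0.0])
        assert out == 0.75
        assert "degenerate" in caplog.text

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="elbow undefined"):
            elbow_threshold([1.0, 0.5])


class TestOverlap:
    def test_per_gene_counts_and_total(self):
        comps = [C(f"c{i}", "h", 0.8) for i in range(3)]
        inter = [
            I("c0", "PTGS2", 0.9),
            I("c1", "PTGS2", 0.9),
            I("c2", "HRH1", 0.9),
            I("c2", "OFF", 0.9),
        ]
        net = build_network(comps, inter)
        table = overlap_with_disease(net, {"PTGS2", "HRH1", "CFTR"})
        assert table.per_herb_gene_counts["h"] == {"PTGS2": 2, "HRH1": 1}
        assert table.total_interactions("h") == 3
        assert table.overlapped_genes("h") == {"PTGS2", "HRH1"}

    def test_herb_without_disease_targets_excluded_from_count(self):
        comps = [C("c1", "hit", 0.8), C("c2", "miss", 0.8)]
        inter = [I("c1", "PTGS2", 0.9), I("c2", "OFF", 0.9)]
        net = build_network(comps, inter)
        table = overlap_with_disease(net, {"PTGS2"})
        assert table.n_herbs_with_overlap == 1
        assert table.total_interactions("miss") == 0

    def test_totals_equal_per_gene_sums_on_generator_output(self):
        herbs = [f"hrb{i:04d}" for i in range(1, 4)]
        compounds, _ = generate_compound_tables(herbs, seed=9)
        interactions, truth = generate_interactions(
            compounds, herb_groups={h: 0 for h in herbs}, seed=9
        )
        net = build_network(
            filter_druglike(compounds), filter_confident(interactions)
        )
        disease = frozenset(truth.data["group_pools"]["0"][:20])
        table = overlap_with_disease(net, disease)
        # independent oracle: flat pandas scan of the raw records
        cdf = pd.DataFrame([(c.compound_id, c.herb_id, c.qed) for c in compounds],
                           columns=["cid", "herb", "qed"])
        idf = pd.DataFrame([(r.compound_id, r.target_gene, r.confidence) for r in interactions],
                           columns=["cid", "gene", "conf"])
        merged = idf[idf.conf > 0.7].merge(cdf[cdf.qed > 0.35], on="cid")
        merged = merged[merged.gene.isin(disease)].drop_duplicates(["cid", "gene"])
        for herb in net.herbs:
            expected = len(merged[merged.herb == herb])
            assert table.total_interactions(herb) == expected
            assert table.total_interactions(herb) == sum(
                table.per_herb_gene_counts.get(herb, {}).values()
            )
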