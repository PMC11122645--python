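"""Calibration sweep for the synthetic-data generator defaults.

Checks that, under the default generator parameter sets, each pipeline
stage's planted-recovery test succeeds in >= 95% of 20 seeds, and reports
the global-null p-value calibration of the enrichment test.  Run once when
choosing defaults:

    python scripts/calibrate.py
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

import herbnet as hn

N_SEEDS = 20


def tfidf_recovery() -> float:
    wins = 0
    for seed in range(N_SEEDS):
        corpus, truth = hn.generate_prescription_corpus(seed=seed)
        selected = {s.herb for s in hn.tfidf_scores(corpus) if s.selected}
        wins += selected == set(truth.data["planted_specific_herbs"])
    return wins / N_SEEDS


def clustering_recovery() -> float:
    wins = 0
    herbs = [f"hrb{i:04d}" for i in range(1, 11)]
    groups = {h: (0 if i < 4 else 1 if i < 7 else 2) for i, h in enumerate(herbs)}
    for seed in range(N_SEEDS):
        compounds, _ = hn.generate_compound_tables(herbs, seed=seed)
        interactions, truth = hn.generate_interactions(
            compounds, herb_groups=groups, seed=seed
        )
        net = hn.build_network(
            hn.filter_druglike(compounds), hn.filter_confident(interactions)
        )
        feats = hn.feature_vectors(net, level="target")
        assign = hn.cut_dendrogram(hn.ward_cluster(feats), level=2)
        labels_true = [groups[h] for h in feats.index]
        labels_pred = [assign[h] for h in feats.index]
        wins += adjusted_rand_score(labels_true, labels_pred) == 1.0
    return wins / N_SEEDS


def louvain_recovery() -> float:
    wins = 0
    for seed in range(N_SEEDS):
        edges, truth = hn.generate_ppi_sbm(
            n_nodes=60, n_blocks=3, p_in=0.5, p_out=0.02, seed=seed
        )
        blocks = truth.data["blocks"]
        graph = hn.build_ppi(edges, set(blocks))
        part = hn.louvain_partition(graph, seed=seed)
        nodes = sorted(blocks)
        ari = adjusted_rand_score(
            [blocks[n] for n in nodes], [part.assignment[n] for n in nodes]
        )
        wins += ari == 1.0
    return wins / N_SEEDS


def null_calibration(n_queries: int = 1000, seed: int = 0) -> float:
    library, _, _ = hn.generate_geneset_library(planted_terms=0, seed=seed)
    rng = np.random.default_rng(seed)
    background = sorted(library.background)
    frac = []
    for _ in range(n_queries):
        query = frozenset(rng.choice(background, size=80, replace=False))
        ps = [
            hn.fisher_enrichment(query, library.sets[t], library.background)
            for t in library.terms
        ]
        frac.append(np.mean(np.asarray(ps) < 0.05))
    return float(np.mean(frac))


if __name__ == "__main__":
    print(f"tfidf planted recovery:      {tfidf_recovery():.2f}")
    print(f"clustering planted recovery: {clustering_recovery():.2f}")
    print(f"louvain planted recovery:    {louvain_recovery():.2f}")
    print(f"null p<0.05 fraction:        {null_calibration():.4f}")
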