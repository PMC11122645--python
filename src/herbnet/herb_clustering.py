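"""Herb clustering by compound- and target-profile similarity.

Herbs are represented as binary feature vectors — which compounds they
contain, or which genes any of their compounds target — and compared with
cosine similarity.  Grouping uses Ward's minimum-variance agglomerative
clustering on Euclidean distances between the binary rows (the behavior of
the standard toolkits that pair a cosine heatmap with a Ward dendrogram);
an average-linkage variant on 1 - cosine is available via ``linkage_on``.
Cutting the dendrogram at level L removes the top L merges and yields L+1
groups; the default cut at level 2 gives three groups.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics.pairwise import cosine_similarity

from .network_assembly import TripartiteNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "HerbDendrogram",
    "feature_vectors",
    "cosine_matrix",
    "ward_cluster",
    "cut_dendrogram",
    "dendrogram_to_newick",
]


class HerbDendrogram:
    """A linkage matrix plus the herb labels of its leaves."""

    def __init__(self, linkage: np.ndarray, labels: list[str], method: str) -> None:
        self.linkage = linkage
        self.labels = list(labels)
        self.method = method

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]


def feature_vectors(
    network: TripartiteNetwork, level: str = "target"
) -> pd.DataFrame:
    """Binary herb-by-feature indicator matrix at the compound or target level.

    At level="target", herb h has a 1 in column g iff any compound of h
    targets g (union semantics).  Herbs with no features are dropped with a
    warning; rows and columns are sorted for canonical order.
    """
    if level not in ("compound", "target"):
        raise ValueError(f"level must be 'compound' or 'target', got {level!r}")
    if not network.herb_compound_edges:
        raise ValueError("empty network")
    rows: dict[str, frozenset[str]] = {}
    for herb in network.herbs:
        feats = (
            network.compounds_of(herb) if level == "compound" else network.targets_of(herb)
        )
        if feats:
            rows[herb] = feats
        else:
            logger.warning("herb %r has no %s features; dropped", herb, level)
    if not rows:
        raise ValueError("no herb has any features at this level")
    columns = sorted(frozenset().union(*rows.values()))
    herbs = sorted(rows)
    data = np.zeros((len(herbs), len(columns)), dtype=int)
    col_idx = {c: j for j, c in enumerate(columns)}
    for i, herb in enumerate(herbs):
        for f in rows[herb]:
            data[i, col_idx[f]] = 1
    return pd.DataFrame(data, index=herbs, columns=columns)


def cosine_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine similarity of feature rows; symmetric with unit diagonal."""
    X = features.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        bad = [features.index[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero feature vectors for herbs: {bad}")
    S = cosine_similarity(X)
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=features.index, columns=features.index)


def ward_cluster(
    features: pd.DataFrame, linkage_on: str = "euclidean"
) -> HerbDendrogram:
    """Agglomerative dendrogram over the herbs of a feature matrix.

    The default applies Ward's minimum-variance criterion to Euclidean
    distances between the binary rows.  ``linkage_on="cosine"`` instead
    applies average linkage to 1 - cosine similarity.
    """
    if len(features) < 2:
        raise ValueError("clustering undefined for a single herb")
    features = features.sort_index()  # invariance to herb input order
    if linkage_on == "euclidean":
        Z = hierarchy.linkage(features.to_numpy(dtype=float), method="ward")
        method = "ward-euclidean"
    elif linkage_on == "cosine":
        D = 1.0 - cosine_matrix(features).to_numpy()
        np.fill_diagonal(D, 0.0)
        Z = hierarchy.linkage(squareform(D, checks=False), method="average")
        method = "average-cosine"
    else:
        raise ValueError(f"linkage_on must be 'euclidean' or 'cosine', got {linkage_on!r}")
    return HerbDendrogram(linkage=Z, labels=list(features.index), method=method)


def cut_dendrogram(dendrogram: HerbDendrogram, level: int = 2) -> dict[str, int]:
    """Group assignment after removing the top `level` merges (level+1 groups).

    Groups are labeled 1..level+1 by descending size; ties break on the
    smallest member herb id.
    """
    n = dendrogram.n_leaves
    if not 1 <= level < n:
        raise ValueError(f"cut level must be in [1, {n - 1}], got {level}")
    flat = hierarchy.cut_tree(dendrogram.linkage, n_clusters=level + 1).ravel()
    members: dict[int, list[str]] = {}
    for herb, g in zip(dendrogram.labels, flat):
        members.setdefault(int(g), []).append(herb)
    ordered = sorted(members.values(), key=lambda m: (-len(m), min(m)))
    return {herb: gi for gi, group in enumerate(ordered, start=1) for herb in group}


def dendrogram_to_newick(dendrogram: HerbDendrogram) -> str:
    """Newick string with merge heights as branch lengths."""
    tree = hierarchy.to_tree(dendrogram.linkage)
    labels = dendrogram.labels

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
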