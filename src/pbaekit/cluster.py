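"""Hierarchical clustering of polymers from standardized descriptors.

Manhattan (city-block) distance between polymers and complete linkage
between clusters: the inter-cluster distance is the maximum over cross-pair
leaf distances, so merge heights are guaranteed nondecreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .library import PolymerID

__all__ = [
    "DistanceMatrix",
    "ClusterTree",
    "manhattan_distance_matrix",
    "complete_linkage",
    "cut_tree",
    "tree_to_newick",
    "tree_to_merge_table",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative polymer × polymer distance matrix."""

    ids: list[PolymerID]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("id list does not match matrix size")
        if not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite")
        if np.max(np.abs(v - v.T)) > 0:
            raise ValueError("distance matrix must be exactly symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterTree:
    """Agglomerative merge history (n−1 merges) over the library.

    ``merges`` rows are (member_a, member_b, height) where members < n are
    leaves and member n+k refers to the cluster created by merge k.
    """

    ids: list[PolymerID]
    merges: np.ndarray       # (n-1, 3)
    linkage_matrix: np.ndarray  # scipy format, for plotting/cutting

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def leaf_order(self) -> list[int]:
        return list(hierarchy.leaves_list(self.linkage_matrix))


def manhattan_distance_matrix(z: np.ndarray, ids=None) -> DistanceMatrix:
    """d_ij = Σ_k |z_ik − z_jk| on the (standardized) descriptor rows."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(z)):
        raise ValueError("input contains NaN/inf")
    if ids is None:
        ids = [PolymerID("A", i + 1) for i in range(z.shape[0])]
    d = squareform(pdist(z, metric="cityblock"))
    d = np.maximum(d, d.T)  # enforce exact symmetry against fp asymmetry
    return DistanceMatrix(list(ids), d)


def complete_linkage(d: DistanceMatrix) -> ClusterTree:
    """Agglomerate with complete (maximum) linkage.

    At each step the pair of clusters with minimal inter-cluster distance is
    merged at that distance, where the inter-cluster distance is the maximum
    over cross-pair leaf distances.
    """
    condensed = squareform(d.values, checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    merges = Z[:, :3].copy()
    return ClusterTree(ids=list(d.ids), merges=merges, linkage_matrix=Z)


def cut_tree(tree: ClusterTree, k: int) -> np.ndarray:
    """Labels for the partition obtained by undoing the last k−1 merges."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    labels = hierarchy.cut_tree(tree.linkage_matrix, n_clusters=k).ravel()
    return labels.astype(int)


def tree_to_newick(tree: ClusterTree) -> str:
    """Serialize to Newick; branch lengths are differences of merge heights."""
    root, _ = hierarchy.to_tree(tree.linkage_matrix, rd=True)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{tree.ids[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right}):0;"


def tree_to_merge_table(tree: ClusterTree) -> pd.DataFrame:
    """Merge history as a tidy table (step, member_a, member_b, height)."""
    rows = [
        (s + 1, int(a), int(b), h)
        for s, (a, b, h) in enumerate(tree.merges)
    ]
    return pd.DataFrame(rows, columns=["step", "member_a", "member_b", "height"])
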