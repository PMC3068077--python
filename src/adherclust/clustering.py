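"""Ward minimum-variance hierarchical clustering of feature vectors.

Linkage follows the minimum-variance criterion: the cost of merging
clusters I and J is the increase in within-cluster sum of squares,

    d(I, J) = n_I * n_J / (n_I + n_J) * ||mean_I - mean_J||^2,

updated with the Lance-Williams recurrence. Merge heights are reported on
this SS-increment scale (two singletons merge at half their squared
Euclidean distance). Cutting the tree to k clusters undoes the last k-1
merges; cluster labels 1..k are assigned by decreasing cluster size (ties
broken by the smallest contained subject index) so that labelling is
deterministic and independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy as _hier

from .markov_features import FeatureVector

__all__ = ["MergeTree", "ClusterAssignment", "ward_linkage", "cut_tree", "cross_tabulate"]


@dataclass(frozen=True)
class MergeTree:
    """Agglomerative merge tree: N-1 merges with SS-increment heights.

    ``merges`` follows the scipy linkage layout: row m = (left, right,
    height, size) where nodes 0..N-1 are leaves and node N+m is the cluster
    created by merge m. Heights are within-SS increments, non-decreasing.
    """

    merges: np.ndarray
    n_leaves: int

    def __post_init__(self) -> None:
        m = np.asarray(self.merges, dtype=float)
        object.__setattr__(self, "merges", m)
        if m.shape != (self.n_leaves - 1, 4):
            raise ValueError("merge table must have N-1 rows of 4 columns")
        h = m[:, 2]
        if (h < -1e-12).any():
            raise ValueError("negative merge height")
        if (np.diff(h) < -1e-9).any():
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaves_of(self, node: int) -> frozenset[int]:
        """Leaf set under an internal or leaf node index."""
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            if n < self.n_leaves:
                out.append(n)
            else:
                stack.extend(self.merges[n - self.n_leaves, :2].astype(int))
        return frozenset(out)

    def leaf_order(self) -> list[int]:
        """Left-to-right dendrogram leaf order."""
        return _hier.leaves_list(self._scipy_linkage()).tolist()

    def _scipy_linkage(self) -> np.ndarray:
        return self.merges

    def to_newick(self, leaf_labels: list[str] | None = None) -> str:
        """Newick string with branch lengths = height gaps between merges."""
        if leaf_labels is None:
            leaf_labels = [f"s{i + 1}" for i in range(self.n_leaves)]
        if len(leaf_labels) != self.n_leaves:
            raise ValueError("one label per leaf required")
        heights = {i: 0.0 for i in range(self.n_leaves)}
        for m, row in enumerate(self.merges):
            heights[self.n_leaves + m] = row[2]

        # iterative post-order assembly (trees can be deep when many
        # identical points chain-merge at height zero)
        rendered: dict[int, str] = {}
        root = 2 * self.n_leaves - 2
        stack = [(root, heights[root], False)]
        while stack:
            node, parent_h, expanded = stack.pop()
            blen = parent_h - heights[node]
            if node < self.n_leaves:
                rendered[node] = f"{leaf_labels[node]}:{blen:.10g}"
                continue
            left, right = self.merges[node - self.n_leaves, :2].astype(int)
            if not expanded:
                stack.append((node, parent_h, True))
                stack.append((left, heights[node], False))
                stack.append((right, heights[node], False))
            else:
                body = f"({rendered.pop(left)},{rendered.pop(right)})"
                rendered[node] = body if node == root else f"{body}:{blen:.10g}"
        return rendered[root] + ";"


@dataclass(frozen=True)
class ClusterAssignment:
    """Per-subject cluster labels in 1..k, aligned with cohort order."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", lab)
        present = np.unique(lab)
        if len(present) != self.k or present.min() < 1 or present.max() > self.k:
            raise ValueError(
                f"labels must use exactly the values 1..{self.k}; got {present.tolist()}"
            )

    def sizes(self) -> np.ndarray:
        """Cluster sizes indexed by label-1."""
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        X = np.asarray(features, dtype=float)
    else:
        rows = [
            f.values if isinstance(f, FeatureVector) else np.asarray(f, dtype=float)
            for f in features
        ]
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError(f"feature vectors have mixed lengths {sorted(lengths)}")
        X = np.vstack(rows)
    if X.ndim != 2:
        raise ValueError("features must form an (N, d) matrix")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects to cluster")
    return X


def ward_linkage(features) -> MergeTree:
    """Ward's minimum-variance linkage of feature vectors.

    Accepts an (N, d) array or a list of equal-length
    :class:`~adherclust.markov_features.FeatureVector`. Heights are
    within-SS increments.
    """
    X = _as_matrix(features)
    Z = _hier.linkage(X, method="ward")
    Z = Z.copy()
    # Euclidean-scale Ward height -> SS increment; strictly monotone, so
    # merge order and node numbering are unchanged
    Z[:, 2] = Z[:, 2] ** 2 / 2.0
    return MergeTree(Z, X.shape[0])


def cut_tree(tree: MergeTree, k: int) -> ClusterAssignment:
    """Cut the merge tree into exactly k clusters (undo the last k-1 merges)."""
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range 1..{n}")
    raw = _hier.cut_tree(tree._scipy_linkage(), n_clusters=k).ravel()
    return _relabel_by_size(raw, k)


def _relabel_by_size(raw: np.ndarray, k: int) -> ClusterAssignment:
    """Map arbitrary group codes to 1..k by decreasing size, ties by first index."""
    groups = {}
    for idx, g in enumerate(raw):
        groups.setdefault(g, []).append(idx)
    ordered = sorted(groups.values(), key=lambda m: (-len(m), m[0]))
    labels = np.empty(len(raw), dtype=int)
    for new, members in enumerate(ordered, start=1):
        labels[members] = new
    return ClusterAssignment(labels, k)


def cross_tabulate(a: ClusterAssignment, b: ClusterAssignment) -> np.ndarray:
    """k_a x k_b contingency table of joint cluster memberships."""
    la, lb = np.asarray(a.labels), np.asarray(b.labels)
    if la.shape != lb.shape:
        raise ValueError("assignments cover different numbers of subjects")
    table = np.zeros((a.k, b.k), dtype=int)
    np.add.at(table, (la - 1, lb - 1), 1)
    return table
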