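"""Fuzzy partition-membership feature transform.

A partition generator (a decision tree fitted on the labelled feature
table) carves feature space into cells; each instance is then re-expressed
as its vector of membership degrees in those cells.  Two modes:

* ``crisp`` — degree 1 in the unique leaf containing the instance, 0
  elsewhere (a one-hot leaf embedding, the hard-partition behaviour of
  WEKA-style partition-membership filters);
* ``graded`` — genuinely fuzzy membership: each split contributes a
  logistic activation sigma(+/-(x_f - t) / bandwidth_f) and a leaf's degree
  is the product along its root-to-leaf path.  Because the two activations
  at every split sum to one, leaf degrees always sum to one, and as the
  bandwidth shrinks the graded degrees converge to the crisp assignment.

The transform is sparse by design: crisp rows have a single nonzero and
graded rows concentrate mass on the few leaves near the instance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.tree import DecisionTreeClassifier


@dataclass
class PartitionConfig:
    """Settings of the tree partition generator."""

    min_leaf: int = 2
    max_depth: int | None = None
    mode: str = "crisp"  # or "graded"
    bandwidth: float | np.ndarray | str = "auto"  # "auto" = 0.25 * per-feature IQR


class PartitionModel:
    """A fitted tree partition with per-cell membership functions.

    Cells are the leaves of a CART tree (Gini impurity, deterministic).
    Use :meth:`membership` for one instance or :meth:`transform` for a
    table; both honour the model's ``mode`` unless overridden.
    """

    def __init__(self, tree: DecisionTreeClassifier, mode: str,
                 bandwidth: np.ndarray):
        self._tree = tree
        t = tree.tree_
        self.mode = mode
        self.bandwidth = bandwidth
        self.n_features = tree.n_features_in_
        self.leaves = np.flatnonzero(t.children_left == -1)
        self._leaf_pos = {int(node): i for i, node in enumerate(self.leaves)}
        # Root-to-leaf paths: list of (feature, threshold, go_right) per leaf.
        self._paths: list[list[tuple[int, float, bool]]] = []
        for leaf in self.leaves:
            self._paths.append(self._path_to(int(leaf)))

    def _path_to(self, leaf: int) -> list[tuple[int, float, bool]]:
        t = self._tree.tree_
        parent = {int(t.children_left[n]): (n, False) for n in range(t.node_count)
                  if t.children_left[n] != -1}
        parent.update({int(t.children_right[n]): (n, True) for n in range(t.node_count)
                       if t.children_right[n] != -1})
        path = []
        node = leaf
        while node in parent:
            p, went_right = parent[node]
            path.append((int(t.feature[p]), float(t.threshold[p]), went_right))
            node = p
        return path[::-1]

    @property
    def n_cells(self) -> int:
        return len(self.leaves)

    def cells(self) -> list[list[tuple[int, float, bool]]]:
        """The threshold-predicate conjunction defining each cell."""
        return [list(p) for p in self._paths]

    def describe(self) -> str:
        """Structured text serialization: bandwidths plus, per cell, the
        conjunction of (feature, threshold, side) predicates on its path."""
        lines = [f"mode: {self.mode}",
                 f"n_features: {self.n_features}",
                 f"n_cells: {self.n_cells}",
                 "bandwidth: " + " ".join(f"{b:.6g}" for b in
                                          np.atleast_1d(self.bandwidth))]
        for i, path in enumerate(self._paths):
            preds = " & ".join(
                f"x{feat}{'>' if right else '<='}{thr:.6g}"
                for feat, thr, right in path) or "(root)"
            lines.append(f"cell {i}: {preds}")
        return "\n".join(lines)

    def membership(self, instance: np.ndarray, mode: str | None = None,
                   bandwidth: float | np.ndarray | None = None) -> np.ndarray:
        """Membership degrees of one instance over all cells (sums to 1)."""
        row = self.transform(np.asarray(instance, dtype=float)[None, :],
                             mode=mode, bandwidth=bandwidth)
        return np.asarray(row.todense()).ravel()

    def transform(self, X: np.ndarray, mode: str | None = None,
                  bandwidth: float | np.ndarray | None = None) -> sp.csr_matrix:
        """Sparse n x n_cells membership matrix; rows sum to 1."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got shape {X.shape}"
            )
        mode = mode or self.mode
        if mode == "crisp":
            leaf_ids = self._tree.apply(X)
            cols = np.array([self._leaf_pos[int(l)] for l in leaf_ids])
            return sp.csr_matrix(
                (np.ones(len(X)), (np.arange(len(X)), cols)),
                shape=(len(X), self.n_cells),
            )
        if mode != "graded":
            raise ValueError("mode must be 'crisp' or 'graded'")
        bw = self.bandwidth if bandwidth is None else bandwidth
        bw = np.broadcast_to(np.asarray(bw, dtype=float), (self.n_features,))
        degrees = np.ones((len(X), self.n_cells))
        for j, path in enumerate(self._paths):
            for feat, thr, went_right in path:
                b = max(bw[feat], 1e-300)
                z = (X[:, feat] - thr) / b
                act = _sigmoid(z if went_right else -z)
                degrees[:, j] *= act
        degrees[degrees < 1e-12] = 0.0
        # Renormalise against accumulated floating error; sums are ~1 already.
        sums = degrees.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        return sp.csr_matrix(degrees / sums)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def fit_partition(
    X: np.ndarray,
    y: np.ndarray,
    config: PartitionConfig | None = None,
) -> PartitionModel:
    """Fit the tree partition generator on a labelled feature table.

    Deterministic given data and config.  A single-class input yields a
    degenerate single-cell model (with a warning), never an error, so the
    transform stays total.
    """
    config = config or PartitionConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.size == 0:
        raise ValueError("empty feature table")
    if len(np.unique(y)) < 2:
        warnings.warn("single-class input: degenerate single-cell partition")
        tree = DecisionTreeClassifier(max_depth=1, random_state=0)
        # A one-node tree: fit on a constant target forces a single leaf.
        tree.fit(np.zeros((2, X.shape[1])), [0, 0])
    else:
        tree = DecisionTreeClassifier(
            criterion="gini",
            min_samples_leaf=config.min_leaf,
            max_depth=config.max_depth,
            random_state=0,
        )
        tree.fit(X, y)
    if isinstance(config.bandwidth, str) and config.bandwidth == "auto":
        q75, q25 = np.percentile(X, [75, 25], axis=0)
        iqr = q75 - q25
        fallback = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        bw = np.where(iqr > 0, 0.25 * iqr, 0.25 * fallback)
    else:
        bw = np.broadcast_to(np.asarray(config.bandwidth, dtype=float), (X.shape[1],)).copy()
    return PartitionModel(tree, mode=config.mode, bandwidth=bw)


def transform_dataset(
    X: np.ndarray,
    y: np.ndarray | None,
    model: PartitionModel,
    mode: str | None = None,
) -> tuple[sp.csr_matrix, np.ndarray | None]:
    """Map a feature table to its sparse membership table, labels untouched."""
    M = model.transform(np.asarray(X, dtype=float), mode=mode)
    return M, (None if y is None else np.asarray(y))
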