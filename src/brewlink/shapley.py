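"""Shapley-value attribution for tree ensembles.

Implements the polynomial-time, path-dependent Tree SHAP algorithm for
sklearn decision trees and random forests: for each sample, the prediction
is decomposed into a base value (the cover-weighted expectation of the
tree) plus one additive contribution per feature, where the value function
of the underlying cooperative game is the tree-traversal conditional
expectation (features outside the coalition are integrated out by
descending both children weighted by their training cover).

Local accuracy — base value + sum of contributions = model prediction — is
an exact identity of the algorithm and is enforced in the test suite. A
brute-force enumeration oracle (:func:`brute_force_shap`) over all feature
coalitions is provided for validation on small trees.

LightGBM and XGBoost regressors are attributed through their built-in
``pred_contrib`` outputs, which implement the same algorithm.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

__all__ = ["TreeStructure", "tree_shap", "shapley_values", "brute_force_shap", "expected_value"]


@dataclass
class TreeStructure:
    """Flat arrays describing one regression tree.

    Internal nodes: ``feature >= 0`` with left child taken when
    ``x[feature] <= threshold``. Leaves: ``feature == -1``. ``cover`` is
    the (weighted) number of training samples that reached each node.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray
    cover: np.ndarray

    @classmethod
    def from_sklearn(cls, tree) -> "TreeStructure":
        t = tree.tree_
        return cls(
            children_left=t.children_left.copy(),
            children_right=t.children_right.copy(),
            feature=t.feature.copy(),
            threshold=t.threshold.copy(),
            value=t.value.reshape(-1).copy(),
            cover=t.weighted_n_node_samples.copy(),
        )

    def is_leaf(self, j: int) -> bool:
        return self.children_left[j] < 0


def expected_value(tree: TreeStructure, x: np.ndarray | None = None, coalition=frozenset()) -> float:
    """Tree-traversal conditional expectation E[f(x) | x_S] with S = coalition.

    Features in the coalition follow the sample's path; all others are
    integrated out using training covers. With an empty coalition this is
    the tree's base value.
    """

    def rec(j: int) -> float:
        if tree.is_leaf(j):
            return float(tree.value[j])
        f = tree.feature[j]
        l, r = tree.children_left[j], tree.children_right[j]
        if x is not None and f in coalition:
            return rec(l) if x[f] <= tree.threshold[j] else rec(r)
        wl = tree.cover[l] / tree.cover[j]
        wr = tree.cover[r] / tree.cover[j]
        return wl * rec(l) + wr * rec(r)

    return rec(0)


def brute_force_shap(tree: TreeStructure, x: np.ndarray, n_features: int) -> np.ndarray:
    """Exact Shapley values by enumerating all feature coalitions.

    Exponential in ``n_features``; intended as an oracle for validating
    :func:`tree_shap` on tiny trees.
    """
    phi = np.zeros(n_features)
    all_features = list(range(n_features))
    fact = math.factorial
    M = n_features
    for i in all_features:
        rest = [f for f in all_features if f != i]
        for r in range(len(rest) + 1):
            for S in itertools.combinations(rest, r):
                w = fact(len(S)) * fact(M - len(S) - 1) / fact(M)
                gain = expected_value(tree, x, frozenset(S) | {i}) - expected_value(
                    tree, x, frozenset(S)
                )
                phi[i] += w * gain
    return phi


class _Path:
    """The path of unique features maintained by the Tree SHAP recursion.

    Parallel lists: feature index ``d``, zero fraction ``z`` (proportion of
    paths flowing through when the feature is excluded), one fraction ``o``
    (1 or 0 when included), and permutation weight ``w``.
    """

    __slots__ = ("d", "z", "o", "w")

    def __init__(self) -> None:
        self.d: list[int] = []
        self.z: list[float] = []
        self.o: list[float] = []
        self.w: list[float] = []

    def copy(self) -> "_Path":
        p = _Path.__new__(_Path)
        p.d = self.d.copy()
        p.z = self.z.copy()
        p.o = self.o.copy()
        p.w = self.w.copy()
        return p

    def extend(self, pz: float, po: float, pi: int) -> None:
        l = len(self.d)
        self.d.append(pi)
        self.z.append(pz)
        self.o.append(po)
        self.w.append(1.0 if l == 0 else 0.0)
        w = self.w
        for i in range(l - 1, -1, -1):
            w[i + 1] += po * w[i] * (i + 1) / (l + 1)
            w[i] = pz * w[i] * (l - i) / (l + 1)

    def unwind(self, i: int) -> None:
        """Remove feature i from the path, restoring the permutation
        weights to the state before it was extended in."""
        l = len(self.d) - 1
        o_i, z_i = self.o[i], self.z[i]
        n = self.w[l]
        w = self.w
        if o_i != 0:
            for j in range(l - 1, -1, -1):
                t = w[j]
                w[j] = n * (l + 1) / ((j + 1) * o_i)
                n = t - w[j] * z_i * (l - j) / (l + 1)
        else:
            for j in range(l - 1, -1, -1):
                w[j] = w[j] * (l + 1) / (z_i * (l - j))
        del self.d[i]
        del self.z[i]
        del self.o[i]
        self.w.pop()

    def unwound_sum(self, i: int) -> float:
        """Sum of the path weights after hypothetically unwinding feature i."""
        l = len(self.d) - 1
        o_i, z_i = self.o[i], self.z[i]
        n = self.w[l]
        total = 0.0
        if o_i != 0:
            for j in range(l - 1, -1, -1):
                t = n * (l + 1) / ((j + 1) * o_i)
                total += t
                n = self.w[j] - t * z_i * (l - j) / (l + 1)
        else:
            for j in range(l - 1, -1, -1):
                total += self.w[j] * (l + 1) / (z_i * (l - j))
        return total


def tree_shap(tree: TreeStructure, x: np.ndarray, n_features: int) -> np.ndarray:
    """Path-dependent Tree SHAP contributions of one sample for one tree."""
    phi = np.zeros(n_features)

    def recurse(j: int, path: _Path, pz: float, po: float, pi: int) -> None:
        path = path.copy()
        path.extend(pz, po, pi)
        if tree.is_leaf(j):
            v = float(tree.value[j])
            for i in range(1, len(path.d)):
                w = path.unwound_sum(i)
                phi[path.d[i]] += w * (path.o[i] - path.z[i]) * v
            return
        f = int(tree.feature[j])
        l, r = int(tree.children_left[j]), int(tree.children_right[j])
        hot, cold = (l, r) if x[f] <= tree.threshold[j] else (r, l)
        iz = io = 1.0
        if f in path.d[1:]:
            k = path.d.index(f, 1)
            iz, io = path.z[k], path.o[k]
            path.unwind(k)
        cj = tree.cover[j]
        recurse(hot, path, iz * tree.cover[hot] / cj, io, f)
        recurse(cold, path, iz * tree.cover[cold] / cj, 0.0, f)

    recurse(0, _Path(), 1.0, 1.0, -1)
    return phi


def _sklearn_trees(model) -> list[TreeStructure]:
    if isinstance(model, DecisionTreeRegressor):
        return [TreeStructure.from_sklearn(model)]
    if isinstance(model, RandomForestRegressor):
        return [TreeStructure.from_sklearn(e) for e in model.estimators_]
    raise TypeError("not an sklearn tree model")


def shapley_values(model, X) -> tuple[np.ndarray, float]:
    """SHAP matrix (samples × features) and base value for a fitted tree
    ensemble.

    Supports sklearn ``DecisionTreeRegressor`` / ``RandomForestRegressor``
    (in-package algorithm), and ``LGBMRegressor`` / ``XGBRegressor``
    (built-in ``pred_contrib``). Linear models are unsupported — their
    attribution is out of scope.
    """
    Xv = np.asarray(X, float)
    cls = type(model).__name__
    if cls in ("DecisionTreeRegressor", "RandomForestRegressor"):
        trees = _sklearn_trees(model)
        n, p = Xv.shape
        phi = np.zeros((n, p))
        for t in trees:
            for s in range(n):
                phi[s] += tree_shap(t, Xv[s], p)
        phi /= len(trees)
        base = float(np.mean([expected_value(t) for t in trees]))
        return phi, base
    if cls == "LGBMRegressor":
        contrib = model.predict(Xv, pred_contrib=True)
        return contrib[:, :-1], float(contrib[0, -1])
    if cls == "XGBRegressor":
        import xgboost

        dm = xgboost.DMatrix(Xv)
        contrib = model.get_booster().predict(dm, pred_contribs=True)
        return contrib[:, :-1].astype(float), float(contrib[0, -1])
    raise TypeError(
        f"unsupported model {cls}: Shapley attribution is defined for tree ensembles only"
    )
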