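"""Survival trees: recursive binary partitioning with Nelson-Aalen leaves.

A tree is grown on a (bootstrap) sample by maximising the splitting criterion
of :mod:`cureforest.splitting` at every node and stops when a node drops below
``2 * min_node_size`` distinct subjects, runs out of events, becomes
homogeneous, or admits no candidate.  "Unique cases" counts distinct subject
ids, so bootstrap duplicates never inflate a node past the stopping rule.

Each leaf stores the Nelson-Aalen cumulative hazard of its in-bag sample,
evaluated on the forest-wide grid of distinct training event times so that
trees can be averaged pointwise.  The Nelson-Aalen estimator is used (rather
than Kaplan-Meier) because it remains stable in the small leaves a deep
survival tree produces; a Kaplan-Meier-style survival transform is available
for display via ``exp(-chf)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .splitting import SplitCandidate, best_split, nelson_aalen

__all__ = ["TreeNode", "SurvivalTree", "GrowConfig", "grow_tree", "predict_chf"]


@dataclass
class TreeNode:
    # internal node
    split: Optional[SplitCandidate] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    # leaf payload
    chf: Optional[np.ndarray] = None
    n_subjects: int = 0
    n_events: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.split is None


@dataclass
class GrowConfig:
    min_node_size: int = 15
    criterion: str = "score"           # "score" | "logrank"
    mtry: Optional[int] = None         # per-node feature sampling (classical mode)
    quartile_mode: bool = False
    ordered3_dummies: bool = False
    epsilon: float = 1e-6


@dataclass
class SurvivalTree:
    root: TreeNode
    feature_subspace: np.ndarray
    inbag_indices: np.ndarray          # bootstrap multiset of subject indices
    time_grid: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Leaf cumulative hazard for each row of ``X`` (shape n x grid)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], self.time_grid.size))
        self._assign(self.root, X, np.arange(X.shape[0]), out)
        return out

    def _assign(self, node: TreeNode, X, idx, out):
        if idx.size == 0:
            return
        if node.is_leaf:
            out[idx] = node.chf
            return
        x = X[idx, node.split.var]
        if np.any(np.isnan(x)):
            raise ValueError(
                f"missing value at split variable {node.split.var}; impute upstream")
        go_right = node.split.membership(x).astype(bool)
        self._assign(node.left, X, idx[~go_right], out)
        self._assign(node.right, X, idx[go_right], out)

    def leaves(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.left, node.right])
        return out

    def split_variables(self) -> set[int]:
        out, stack = set(), [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.add(node.split.var)
                stack.extend([node.left, node.right])
        return out

    def to_dict(self) -> dict:
        def enc(node: TreeNode):
            if node.is_leaf:
                return {"chf": node.chf.tolist(), "n_subjects": node.n_subjects,
                        "n_events": node.n_events}
            return {"var": node.split.var, "rule": node.split.rule,
                    "threshold": node.split.threshold,
                    "left": enc(node.left), "right": enc(node.right)}
        return {"root": enc(self.root),
                "feature_subspace": self.feature_subspace.tolist(),
                "inbag_indices": self.inbag_indices.tolist(),
                "time_grid": self.time_grid.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalTree":
        def dec(e):
            if "chf" in e:
                return TreeNode(chf=np.asarray(e["chf"], dtype=float),
                                n_subjects=e["n_subjects"], n_events=e["n_events"])
            return TreeNode(split=SplitCandidate(e["var"], e["rule"], e["threshold"]),
                            left=dec(e["left"]), right=dec(e["right"]))
        return cls(root=dec(d["root"]),
                   feature_subspace=np.asarray(d["feature_subspace"], dtype=int),
                   inbag_indices=np.asarray(d["inbag_indices"], dtype=int),
                   time_grid=np.asarray(d["time_grid"], dtype=float))


def _leaf(times, events, ids, grid) -> TreeNode:
    if np.any(events == 1):
        chf = nelson_aalen(times, events)(grid)
    else:
        chf = np.zeros(grid.size)
    return TreeNode(chf=np.asarray(chf, dtype=float),
                    n_subjects=int(np.unique(ids).size),
                    n_events=int(np.sum(events == 1)))


def _unique_mask(ids: np.ndarray) -> np.ndarray:
    _, first = np.unique(ids, return_index=True)
    mask = np.zeros(ids.size, dtype=bool)
    mask[first] = True
    return mask


def grow_tree(X, times, events, kinds, feature_subspace=None,
              config: GrowConfig | None = None, subject_ids=None,
              time_grid=None, rng=None) -> SurvivalTree:
    """Grow one survival tree.

    ``X, times, events, subject_ids`` describe the (bootstrap) sample; rows
    with equal ``subject_ids`` are copies of the same subject.  When
    ``config.mtry`` is set (classical mode), each node independently samples
    ``mtry`` variables from ``feature_subspace``; otherwise every node searches
    the whole subspace.
    """
    X = np.asarray(X, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("cannot grow a tree on an empty sample")
    config = config or GrowConfig()
    n, m = X.shape
    subspace = np.sort(np.asarray(
        np.arange(m) if feature_subspace is None else feature_subspace, dtype=int))
    ids = np.arange(n) if subject_ids is None else np.asarray(subject_ids)
    if time_grid is None:
        time_grid = np.unique(times[np.asarray(events) == 1])
    grid = np.asarray(time_grid, dtype=float)
    if config.mtry is not None and rng is None:
        rng = np.random.default_rng(0)

    def build(idx: np.ndarray) -> TreeNode:
        t, e, i = times[idx], events[idx], ids[idx]
        umask = _unique_mask(i)
        n_unique = int(umask.sum())
        if (n_unique < 2 * config.min_node_size or not np.any(e == 1)
                or _homogeneous(X[idx][:, subspace], t, e)):
            return _leaf(t, e, i, grid)
        feats = subspace
        if config.mtry is not None:
            k = min(config.mtry, subspace.size)
            feats = np.sort(rng.choice(subspace, size=k, replace=False))
        found = best_split(
            t, e, X[idx], kinds, feature_ids=feats, criterion=config.criterion,
            min_node_size=config.min_node_size, unique_mask=umask,
            quartile_mode=config.quartile_mode,
            ordered3_dummies=config.ordered3_dummies, epsilon=config.epsilon)
        if found is None:
            return _leaf(t, e, i, grid)
        cand, _ = found
        member = cand.membership(X[idx, cand.var]).astype(bool)
        node = TreeNode(split=cand)
        node.left = build(idx[~member])
        node.right = build(idx[member])
        return node

    root = build(np.arange(n))
    return SurvivalTree(root=root, feature_subspace=subspace,
                        inbag_indices=ids.copy(), time_grid=grid)


def _homogeneous(Xs, t, e) -> bool:
    """All subjects share identical outcomes and (subspace) feature values."""
    if np.ptp(t) > 0 or np.ptp(e) > 0:
        return False
    return bool(np.all(Xs == Xs[0]))


def predict_chf(tree: SurvivalTree, x) -> np.ndarray:
    """Drop one subject down the tree; return the reached leaf's CHF."""
    return tree.predict(np.atleast_2d(x))[0]
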