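"""Random survival forests with per-tree random feature subspaces.

Three construction modes share bootstrap resampling and differ in how the
feature space is randomised:

- ``subspace``  (the modified RSF): each tree draws, once, a random subset of
  ``ceil(fraction * m)`` variables without replacement; every node of that tree
  searches all of them.  With a tiny fraction of relevant predictors hidden in
  tens of thousands of noise variables, this keeps the per-tree search wide
  enough to find the signal while the per-tree subspaces still decorrelate the
  ensemble.
- ``classical`` (standard RSF): every node independently samples
  ``ceil(sqrt(m))`` candidate variables.
- ``bagging``   the special case where every variable is a candidate at every
  node, implemented as ``subspace`` with fraction fixed at 1.0 (which makes the
  fraction-1.0 / bagging equivalence exact by construction).

Out-of-bag (OOB) prediction averages, for each subject, only the trees whose
bootstrap sample excludes that subject; with ``B`` trees a subject is in-bag
everywhere with probability about ``0.632^B`` and is then reported as missing
rather than silently substituted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data_model import Cohort
from .tree import GrowConfig, SurvivalTree, grow_tree

__all__ = ["ForestConfig", "SurvivalForest", "PredictionResult", "fit_forest",
           "predict_ensemble_chf", "oob_predict", "mortality"]


@dataclass
class ForestConfig:
    n_trees: int = 500
    mode: str = "subspace"             # "subspace" | "classical" | "bagging"
    subsample_fraction: float = 0.75   # tree-level feature fraction p*/m (subspace)
    min_node_size: int = 15
    criterion: str = "score"           # "score" | "logrank"
    quartile_mode: bool = False
    ordered3_dummies: bool = False
    epsilon: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.mode not in ("subspace", "classical", "bagging"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.criterion not in ("score", "logrank"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


@dataclass
class PredictionResult:
    """Per-subject ensemble CHF on the training event-time grid.

    ``chf`` is ``n x grid`` (NaN rows where no OOB tree was available when the
    result comes from :func:`oob_predict`); ``available`` flags usable rows;
    ``n_trees_used`` counts the trees that entered each average.
    """

    time_grid: np.ndarray
    chf: np.ndarray
    available: np.ndarray
    n_trees_used: np.ndarray

    def mortality(self) -> np.ndarray:
        return self.chf.sum(axis=1)

    def cdf(self) -> np.ndarray:
        """Event-probability curves ``1 - exp(-CHF)``."""
        return 1.0 - np.exp(-self.chf)


@dataclass
class SurvivalForest:
    trees: list[SurvivalTree]
    time_grid: np.ndarray
    variable_names: list[str]
    kinds: list[str]
    config: ForestConfig
    n_subjects: int

    def inbag_counts(self) -> np.ndarray:
        """``B x n`` bootstrap multiplicities."""
        out = np.zeros((len(self.trees), self.n_subjects), dtype=np.int32)
        for b, tree in enumerate(self.trees):
            np.add.at(out[b], tree.inbag_indices, 1)
        return out

    def to_dict(self) -> dict:
        return {"config": asdict(self.config),
                "time_grid": self.time_grid.tolist(),
                "variable_names": self.variable_names,
                "kinds": self.kinds,
                "n_subjects": self.n_subjects,
                "trees": [t.to_dict() for t in self.trees]}

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalForest":
        return cls(trees=[SurvivalTree.from_dict(t) for t in d["trees"]],
                   time_grid=np.asarray(d["time_grid"], dtype=float),
                   variable_names=list(d["variable_names"]),
                   kinds=list(d["kinds"]),
                   config=ForestConfig(**d["config"]),
                   n_subjects=int(d["n_subjects"]))

    @classmethod
    def load(cls, path) -> "SurvivalForest":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _cohort_arrays(cohort: Cohort):
    if cohort.has_missing():
        raise ValueError("cohort has missing values; run impute_missing first")
    return cohort.as_arrays()


def fit_forest(cohort: Cohort, config: ForestConfig | None = None) -> SurvivalForest:
    """Fit the ensemble.  Fully reproducible from ``config.seed``.

    Per-tree seeds are spawned deterministically up front, so results do not
    depend on evaluation order.
    """
    config = config or ForestConfig()
    X, kinds, names = _cohort_arrays(cohort)
    times, events = cohort.time, cohort.event
    n, m = X.shape
    if n < 2 * config.min_node_size:
        raise ValueError("cohort smaller than twice the minimum node size")
    if not np.any(events == 1):
        raise ValueError("cohort has no events; nothing to model")
    grid = np.unique(times[events == 1])

    mode = config.mode
    fraction = 1.0 if mode == "bagging" else config.subsample_fraction
    p_star = max(1, math.ceil(fraction * m))
    mtry = max(1, math.ceil(math.sqrt(m))) if mode == "classical" else None

    grow_cfg = GrowConfig(min_node_size=config.min_node_size,
                          criterion=config.criterion, mtry=mtry,
                          quartile_mode=config.quartile_mode,
                          ordered3_dummies=config.ordered3_dummies,
                          epsilon=config.epsilon)

    trees = []
    for child in np.random.SeedSequence(config.seed).spawn(config.n_trees):
        rng = np.random.default_rng(child)
        boot = rng.integers(0, n, size=n)
        if mode == "classical":
            subspace = np.arange(m)
        else:
            subspace = np.sort(rng.choice(m, size=p_star, replace=False))
        trees.append(grow_tree(
            X[boot], times[boot], events[boot], kinds,
            feature_subspace=subspace, config=grow_cfg,
            subject_ids=boot, time_grid=grid, rng=rng))
    return SurvivalForest(trees=trees, time_grid=grid, variable_names=names,
                          kinds=kinds, config=config, n_subjects=n)


def predict_ensemble_chf(forest: SurvivalForest, X) -> PredictionResult:
    """Pointwise mean CHF over all trees on the common grid."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    acc = np.zeros((X.shape[0], forest.time_grid.size))
    for tree in forest.trees:
        acc += tree.predict(X)
    acc /= len(forest.trees)
    n = X.shape[0]
    return PredictionResult(time_grid=forest.time_grid, chf=acc,
                            available=np.ones(n, dtype=bool),
                            n_trees_used=np.full(n, len(forest.trees)))


def oob_predict(forest: SurvivalForest, cohort: Cohort) -> PredictionResult:
    """Average each subject's CHF over exactly its out-of-bag trees."""
    X, _, names = _cohort_arrays(cohort)
    if cohort.n != forest.n_subjects or names != forest.variable_names:
        raise ValueError("cohort does not match the one the forest was fit on")
    n = cohort.n
    acc = np.zeros((n, forest.time_grid.size))
    used = np.zeros(n, dtype=int)
    inbag = forest.inbag_counts()
    for b, tree in enumerate(forest.trees):
        oob = np.flatnonzero(inbag[b] == 0)
        if oob.size == 0:
            continue
        acc[oob] += tree.predict(X[oob])
        used[oob] += 1
    available = used > 0
    chf = np.full_like(acc, np.nan)
    chf[available] = acc[available] / used[available, None]
    return PredictionResult(time_grid=forest.time_grid, chf=chf,
                            available=available, n_trees_used=used)


def mortality(chf) -> float | np.ndarray:
    """Ensemble mortality: the CHF summed over the training event-time grid.

    A scalar risk score that preserves pointwise ordering of hazard curves; it
    is the risk ranking fed to the concordance index.
    """
    chf = np.asarray(chf, dtype=float)
    along = chf if chf.ndim == 1 else chf
    diffs = np.diff(along, axis=-1)
    if np.any(diffs < -1e-9):
        raise ValueError("cumulative hazard must be nondecreasing")
    out = chf.sum(axis=-1)
    return float(out) if np.ndim(out) == 0 else out
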