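"""Group separability: DT / SVM / KNN under three validation schemes.

Evaluates how well the feature table separates the groups with a decision
tree, an RBF support vector machine, and k-nearest neighbours, each scored
under stratified 5-fold and 10-fold cross-validation and under
resubstitution ("no validation": train and score on the full table, an
optimistic upper bound).  Also produces plain per-group feature summaries.

Hyperparameters follow common defaults — CART/Gini tree, RBF SVM with
C=1 on standardized features, k=5 Euclidean KNN on standardized features —
and every choice is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ALGORITHMS",
    "SCHEMES",
    "EvalScheme",
    "ClassifierReport",
    "GroupSummary",
    "evaluate",
    "compare_algorithms",
    "group_summary",
]

ALGORITHMS = ("DT", "SVM", "KNN")
SCHEMES = ("cv5", "cv10", "resubstitution")


@dataclass(frozen=True)
class EvalScheme:
    """Validation scheme: stratified k-fold CV or resubstitution."""

    kind: str = "cv5"
    seed: int = 0

    def __post_init__(self):
        if self.kind not in SCHEMES:
            raise ValueError(f"kind must be one of {SCHEMES}, got {self.kind!r}")

    @property
    def n_splits(self) -> int | None:
        return {"cv5": 5, "cv10": 10, "resubstitution": None}[self.kind]


def _make_estimator(algorithm: str, seed: int, params: Mapping | None = None):
    params = dict(params or {})
    algorithm = algorithm.upper()
    if algorithm == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if algorithm == "SVM":
        params.setdefault("kernel", "rbf")
        params.setdefault("C", 1.0)
        return make_pipeline(StandardScaler(), SVC(random_state=seed, **params))
    if algorithm == "KNN":
        params.setdefault("n_neighbors", 5)
        return make_pipeline(StandardScaler(), KNeighborsClassifier(**params))
    raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {algorithm!r}")


def _check_inputs(X: pd.DataFrame | np.ndarray, y: Sequence) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("features and labels must align")
    if np.isnan(X).any():
        raise ValueError("feature table contains NaN cells")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    return X, y


def evaluate(
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    algorithm: str = "DT",
    scheme: EvalScheme | None = None,
    params: Mapping | None = None,
) -> float:
    """Accuracy percentage of one algorithm under one validation scheme.

    Cross-validated accuracy is the plain mean over stratified folds;
    resubstitution fits and scores on the full table.  Deterministic for a
    fixed scheme seed.
    """
    scheme = scheme or EvalScheme()
    X, y = _check_inputs(X, y)
    est = _make_estimator(algorithm, scheme.seed, params)
    if scheme.kind == "resubstitution":
        est.fit(X, y)
        return 100.0 * float(est.score(X, y))
    smallest = int(np.unique(y, return_counts=True)[1].min())
    if smallest < scheme.n_splits:
        raise ValueError(
            f"{scheme.kind} needs at least {scheme.n_splits} subjects per class "
            f"(smallest class has {smallest})"
        )
    cv = StratifiedKFold(n_splits=scheme.n_splits, shuffle=True, random_state=scheme.seed)
    scores = cross_val_score(est, X, y, cv=cv, scoring="accuracy")
    return 100.0 * float(scores.mean())


@dataclass
class ClassifierReport:
    """Accuracy grids (algorithm x scheme), one per classification task."""

    tasks: Mapping[str, pd.DataFrame]

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for task, grid in self.tasks.items():
            g = grid.copy()
            g.insert(0, "task", task)
            parts.append(g.reset_index(names="algorithm"))
        return pd.concat(parts, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.2f")

    def to_json(self, path) -> None:
        import json

        payload = {
            task: grid.round(2).to_dict(orient="index")
            for task, grid in self.tasks.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _default_tasks(y: np.ndarray) -> dict[str, np.ndarray]:
    labels = set(np.unique(y))
    tasks: dict[str, np.ndarray] = {}
    if {"ADHD_pre", "HC"} <= labels:
        tasks["ADHD_pre_vs_HC"] = np.isin(y, ["ADHD_pre", "HC"])
    if len(labels) >= 3:
        tasks["three_group"] = np.ones(len(y), dtype=bool)
    if not tasks:
        tasks["all"] = np.ones(len(y), dtype=bool)
    return tasks


def compare_algorithms(
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    tasks: Mapping[str, np.ndarray] | None = None,
    seed: int = 0,
) -> ClassifierReport:
    """Full 3-algorithm x 3-scheme accuracy grid per classification task.

    Default tasks are drug-free-vs-control (two-class) and the three-group
    problem when the labels provide them; custom tasks are boolean row
    masks.  Identical seeds give identical reports.
    """
    X, y = _check_inputs(X, y)
    task_masks = dict(tasks) if tasks is not None else _default_tasks(y)
    out: dict[str, pd.DataFrame] = {}
    for task, mask in task_masks.items():
        mask = np.asarray(mask, dtype=bool)
        grid = pd.DataFrame(index=list(ALGORITHMS), columns=list(SCHEMES), dtype=float)
        grid.index.name = "algorithm"
        for algo in ALGORITHMS:
            for kind in SCHEMES:
                grid.loc[algo, kind] = evaluate(
                    X[mask], y[mask], algorithm=algo, scheme=EvalScheme(kind, seed)
                )
        out[task] = grid
    return ClassifierReport(tasks=out)


@dataclass
class GroupSummary:
    """Per-group feature means plus group sizes."""

    feature_means: pd.DataFrame      # groups x features
    sizes: pd.Series

    @property
    def cgd_rate(self) -> pd.Series:
        """Colour-rule success percentage per group."""
        return 100.0 * self.feature_means["cgd"]

    @property
    def rsot(self) -> pd.Series:
        return self.feature_means["rsot_weighted"]


def group_summary(features: pd.DataFrame, y: Sequence) -> GroupSummary:
    """Arithmetic mean of every feature per group."""
    y = np.asarray(y)
    if len(features) != len(y):
        raise ValueError("features and labels must align")
    if len(features) == 0:
        raise ValueError("empty feature table")
    grouped = features.groupby(y)
    means = grouped.mean()
    means.index.name = "group"
    sizes = grouped.size()
    sizes.name = "n"
    return GroupSummary(feature_means=means, sizes=sizes)
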