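"""Balanced random-forest stress classifier with subject-grouped validation.

Each tree is grown on a bootstrap sample in which the majority class has
been randomly under-sampled to the minority count, so every tree sees
balanced labels despite the cohort-level imbalance.  The ensemble
probability is the fraction of trees voting "stress" (majority-vote
semantics).  Hyper-parameters are selected by subject-grouped
cross-validated F1 on the stress class, and evaluation uses grouped
k-fold or leave-one-subject-out so no subject ever appears on both sides
of a split.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold, LeaveOneGroupOut
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix
from .registry import FEATURE_NAMES, StressReportError

#: Default hyper-parameter grid for the search.
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [100, 300],
    "max_depth": [4, 8, None],
    "min_samples_leaf": [1, 5],
}


@dataclass
class Tree:
    """Flat decision-tree arrays (sklearn layout: left child is taken when
    x[feature] <= threshold; children == -1 marks a leaf).  ``value`` holds
    the leaf output — the voted class for classifier trees, but arbitrary
    reals are allowed so hand-built regression stumps work too."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(len(X), dtype=np.intp)
        active = self.children_left[node] != -1
        while active.any():
            idx = np.flatnonzero(active)
            cur = node[idx]
            go_left = X[idx, self.feature[cur]] <= self.threshold[cur]
            node[idx] = np.where(
                go_left, self.children_left[cur], self.children_right[cur]
            )
            active = self.children_left[node] != -1
        return self.value[node]

    @property
    def max_depth(self) -> int:
        depth = np.zeros(len(self.children_left), dtype=int)
        order = range(len(depth))
        for i in order:  # parents precede children in sklearn's layout
            for child in (self.children_left[i], self.children_right[i]):
                if child != -1:
                    depth[child] = depth[i] + 1
        return int(depth.max()) if len(depth) else 0

    @classmethod
    def from_sklearn(cls, clf: DecisionTreeClassifier) -> "Tree":
        t = clf.tree_
        votes = clf.classes_[np.argmax(t.value[:, 0, :], axis=1)]
        return cls(
            children_left=t.children_left.copy(),
            children_right=t.children_right.copy(),
            feature=t.feature.copy(),
            threshold=t.threshold.copy(),
            value=votes.astype(float),
        )


@dataclass
class CVResult:
    """Per-fold stress-class F1 scores with fold provenance."""

    fold_f1: list[float]
    fold_test_subjects: list[list[str]]
    fold_train_subjects: list[list[str]]

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": range(len(self.fold_f1)),
                "f1_binary": self.fold_f1,
                "test_subjects": ["|".join(s) for s in self.fold_test_subjects],
            }
        )


@dataclass
class StressModel:
    """Trained balanced tree ensemble plus training metadata."""

    trees: list[Tree]
    feature_names: list[str]
    p_avg: float
    params: dict
    seed: int
    cv: CVResult | None = field(default=None)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        """Vote-fraction stress probability for each row of ``X``."""
        X = np.asarray(X, dtype=float)
        votes = np.zeros(len(X))
        for tree in self.trees:
            votes += tree.predict(X)
        return votes / len(self.trees)


def average_stress_probability(y) -> float:
    """Prevalence of stress in historical labels: Mean(y_train)."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise StressReportError("cannot average an empty label vector")
    return float(np.mean(y))


def balanced_bootstrap_indices(
    rng: np.random.Generator, y: np.ndarray
) -> np.ndarray:
    """Bootstrap row indices, then randomly under-sample the bootstrap's
    majority class down to its minority count.  The returned sample always
    contains both classes with equal counts."""
    n = len(y)
    for _ in range(1000):
        boot = rng.integers(0, n, size=n)
        yb = y[boot]
        n_pos = int(yb.sum())
        if 0 < n_pos < n:
            break
    else:  # pragma: no cover - both classes present in y, so unreachable
        raise StressReportError("could not draw a two-class bootstrap")
    pos = boot[yb == 1]
    neg = boot[yb == 0]
    k = min(len(pos), len(neg))
    pos = rng.permutation(pos)[:k]
    neg = rng.permutation(neg)[:k]
    return np.concatenate([pos, neg])


def _fit_forest(
    X: np.ndarray, y: np.ndarray, params: dict, seed: int
) -> list[Tree]:
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(params.get("n_estimators", 100)):
        idx = balanced_bootstrap_indices(rng, y)
        clf = DecisionTreeClassifier(
            max_depth=params.get("max_depth"),
            min_samples_leaf=params.get("min_samples_leaf", 1),
            max_features=params.get("max_features", "sqrt"),
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        clf.fit(X[idx], y[idx])
        trees.append(Tree.from_sklearn(clf))
    return trees


def _expand_grid(grid) -> list[dict]:
    if grid is None:
        grid = DEFAULT_GRID
    if isinstance(grid, dict):
        keys = list(grid)
        points = [dict(zip(keys, combo)) for combo in itertools.product(*grid.values())]
    else:
        points = [dict(p) for p in grid]
    if not points:
        raise StressReportError("hyper-parameter grid is empty")
    return points


def fit_balanced_rf(
    fm: FeatureMatrix, grid=None, seed: int = 0, cv_k: int = 4
) -> StressModel:
    """Fit the balanced random forest, selecting the grid point with the
    best mean subject-grouped validation F1, then refitting on all rows."""
    X, y, groups = fm.X, fm.y, fm.groups
    if len(np.unique(y)) < 2:
        raise StressReportError("training labels contain a single class")
    points = _expand_grid(grid)
    best = points[0]
    if len(points) > 1:
        n_subjects = len(np.unique(groups))
        k = min(cv_k, n_subjects)
        if k < 2:
            raise StressReportError("grid search needs >= 2 subjects")
        splitter = GroupKFold(n_splits=k)
        scores = []
        for p_idx, params in enumerate(points):
            fold_scores = []
            for f_idx, (tr, te) in enumerate(splitter.split(X, y, groups)):
                if len(np.unique(y[tr])) < 2 or y[te].sum() == 0:
                    continue
                trees = _fit_forest(X[tr], y[tr], params, seed=seed * 10007 + p_idx * 101 + f_idx)
                pred = (_forest_proba(trees, X[te]) >= 0.5).astype(int)
                fold_scores.append(_f1_binary(y[te], pred))
            scores.append(np.mean(fold_scores) if fold_scores else -1.0)
        best = points[int(np.argmax(scores))]
    trees = _fit_forest(X, y, best, seed=seed)
    return StressModel(
        trees=trees,
        feature_names=list(fm.feature_names),
        p_avg=average_stress_probability(y),
        params=dict(best),
        seed=seed,
    )


def _forest_proba(trees: list[Tree], X: np.ndarray) -> np.ndarray:
    votes = np.zeros(len(X))
    for tree in trees:
        votes += tree.predict(X)
    return votes / len(trees)


def _f1_binary(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def predict_stress_probability(model: StressModel, x) -> float:
    """P_X(stress) for one observation: the fraction of trees voting
    stress.  ``x`` may be a mapping/Series keyed by feature name or a
    plain vector in the model's feature order."""
    if isinstance(x, pd.Series):
        x = x.to_dict()
    if isinstance(x, dict):
        missing = [f for f in model.feature_names if f not in x]
        extra = [f for f in x if f not in model.feature_names]
        if missing or extra:
            raise StressReportError(
                f"feature mismatch: missing {missing}, unexpected {extra}"
            )
        vec = np.array([float(x[f]) for f in model.feature_names])
    else:
        vec = np.asarray(x, dtype=float)
        if vec.shape != (model.n_features,):
            raise StressReportError(
                f"expected {model.n_features} features, got shape {vec.shape}"
            )
    return float(model.predict_proba_matrix(vec[None, :])[0])


def grouped_cross_validate(
    fm: FeatureMatrix, k: int | str = 4, grid=None, seed: int = 0
) -> CVResult:
    """Subject-grouped k-fold (or ``k="loso"`` leave-one-subject-out)
    cross-validation; folds partition subjects, never rows."""
    X, y, groups = fm.X, fm.y, fm.groups
    subjects = np.unique(groups)
    if k == "loso":
        if len(subjects) < 2:
            raise StressReportError("LOSO needs >= 2 subjects")
        splitter = LeaveOneGroupOut()
    else:
        k = int(k)
        if k > len(subjects):
            raise StressReportError(f"k={k} exceeds {len(subjects)} subjects")
        if k < 2:
            raise StressReportError("k must be >= 2")
        splitter = GroupKFold(n_splits=k)
    fold_f1, test_subj, train_subj = [], [], []
    for f_idx, (tr, te) in enumerate(splitter.split(X, y, groups)):
        sub_fm = fm.subset(np.isin(np.arange(len(fm)), tr))
        model = fit_balanced_rf(sub_fm, grid=grid, seed=seed * 7919 + f_idx)
        pred = (model.predict_proba_matrix(X[te]) >= 0.5).astype(int)
        fold_f1.append(_f1_binary(y[te], pred))
        test_subj.append(sorted(set(groups[te])))
        train_subj.append(sorted(set(groups[tr])))
    return CVResult(fold_f1=fold_f1, fold_test_subjects=test_subj,
                    fold_train_subjects=train_subj)


# ---------------------------------------------------------------------------
# JSON persistence


def save_model(model: StressModel, path) -> None:
    doc = {
        "feature_names": model.feature_names,
        "p_avg": model.p_avg,
        "params": {k: v for k, v in model.params.items()},
        "seed": model.seed,
        "trees": [
            {
                "children_left": t.children_left.tolist(),
                "children_right": t.children_right.tolist(),
                "feature": t.feature.tolist(),
                "threshold": t.threshold.tolist(),
                "value": t.value.tolist(),
            }
            for t in model.trees
        ],
        "cv": None
        if model.cv is None
        else {
            "fold_f1": model.cv.fold_f1,
            "fold_test_subjects": model.cv.fold_test_subjects,
            "fold_train_subjects": model.cv.fold_train_subjects,
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)


def load_model(path) -> StressModel:
    with open(path) as fh:
        doc = json.load(fh)
    trees = [
        Tree(
            children_left=np.asarray(t["children_left"], dtype=np.intp),
            children_right=np.asarray(t["children_right"], dtype=np.intp),
            feature=np.asarray(t["feature"], dtype=np.intp),
            threshold=np.asarray(t["threshold"], dtype=float),
            value=np.asarray(t["value"], dtype=float),
        )
        for t in doc["trees"]
    ]
    cv = None
    if doc.get("cv"):
        cv = CVResult(
            fold_f1=doc["cv"]["fold_f1"],
            fold_test_subjects=doc["cv"]["fold_test_subjects"],
            fold_train_subjects=doc["cv"]["fold_train_subjects"],
        )
    return StressModel(
        trees=trees,
        feature_names=list(doc["feature_names"]),
        p_avg=float(doc["p_avg"]),
        params=dict(doc["params"]),
        seed=int(doc["seed"]),
        cv=cv,
    )
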