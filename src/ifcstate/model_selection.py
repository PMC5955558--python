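"""Cross-validated model selection and imbalance-aware evaluation.

The labeled data ``D`` is split once into a model-selection part ``D_MS``
and a held-out test part; candidates (classifier hyperparameters together
with the number of retained features ``n_FS``) are compared by stratified
K-fold cross-validation on ``D_MS`` only, and the winner is refitted on
all of ``D_MS`` and scored once on the untouched test part.

Within every fold iteration, the scaler *and* the filter ranking are
fitted on the K-1 training subsets only and then applied to the left-out
subset — validation labels and values never influence any fitted
parameter.  Metrics: plain accuracy (mean 0-1 gain) and, for imbalanced
data, the geometric mean of the class-specific accuracies, which drops to
zero when any class is ignored entirely.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .classifiers import ClassifierSpec, TrainedModel, predict, train_classifier
from .feature_table import FeatureTable
from .feature_filters import FilterRanking, rank_features, select_top
from .preprocessing import apply_scaler, fit_scaler

logger = logging.getLogger("ifcstate")

__all__ = [
    "CVPlan",
    "SearchSpace",
    "EvaluationReport",
    "ModelSelectionResult",
    "stratified_folds",
    "accuracy",
    "class_metrics",
    "fit_candidate",
    "cross_validate",
    "grid_search",
    "random_search",
    "DEFAULT_GRIDS",
]

#: default hyperparameter grids, overridable per search
DEFAULT_GRIDS: dict[str, list] = {
    "n_fs": [1, 2, 5, 10, 20, 50, "all"],
    "k": [1, 3, 5, 11, 21, 51],
    "C": [2.0**e for e in range(-5, 16, 2)],
    "gamma": [2.0**e for e in range(-15, 4, 2)],
    "landmarks": [100],
}

#: class-imbalance ratio beyond which the geometric mean is suggested
_IMBALANCE_WARN_RATIO = 5.0


@dataclass
class CVPlan:
    """A fold assignment for K-fold cross-validation."""

    n_folds: int
    seed: int
    fold_assignment: np.ndarray
    stratified: bool = True

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, validation_idx) for one fold."""
        val = np.nonzero(self.fold_assignment == fold)[0]
        train = np.nonzero(self.fold_assignment != fold)[0]
        return train, val


@dataclass
class SearchSpace:
    """Hyperparameter search space for one filter/classifier combination."""

    filter_method: str = "MIM"
    classifier: str = "LDA"
    scaling: str = "standardize"
    n_bins: int = 10
    priors: str = "equal"
    grids: dict[str, list] = field(default_factory=dict)
    per_fold_ranking: bool = True
    seed: int = 0

    def grid(self, name: str) -> list:
        return list(self.grids.get(name, DEFAULT_GRIDS[name]))

    def candidate_params(self) -> list[str]:
        """Grid names the chosen classifier actually uses."""
        names = ["n_fs"]
        method = self.classifier.upper()
        if method == "KNN":
            names.append("k")
        elif method == "LLSVM":
            names += ["C", "gamma", "landmarks"]
        return names


@dataclass
class EvaluationReport:
    """Accuracy, class-specific accuracies, geometric mean, confusion matrix.

    The confusion matrix has true classes on rows and predicted classes on
    columns, both in ``class_names`` order (order of first appearance in
    the training data).
    """

    class_names: list[str]
    accuracy: float
    class_accuracies: dict[str, float]
    geometric_mean: float
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "accuracy": self.accuracy,
            "class_accuracies": dict(self.class_accuracies),
            "geometric_mean": self.geometric_mean,
            "confusion": self.confusion.tolist(),
        }


@dataclass
class ModelSelectionResult:
    """All evaluated candidates, the winner, and the final test report."""

    candidates: list[dict]
    winner: dict
    model: TrainedModel
    ranking: FilterRanking | None = None
    test_report: EvaluationReport | None = None


def stratified_folds(
    labels: np.ndarray, n_folds: int, seed: int = 0
) -> CVPlan:
    """Assign rows to K folds preserving class composition.

    Within every class the (shuffled) members are dealt cyclically,
    continuing a global fold pointer, so fold sizes differ by at most one
    overall and per class.  Deterministic per seed.
    """
    labels = np.asarray(labels, dtype=object)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    class_names = list(dict.fromkeys(labels))
    rng = np.random.default_rng(seed)
    assignment = np.full(len(labels), -1)
    pointer = 0
    for c in class_names:
        idx = np.nonzero(labels == c)[0]
        if len(idx) < n_folds:
            raise ValueError(
                f"class '{c}' has {len(idx)} members, fewer than {n_folds} folds"
            )
        idx = rng.permutation(idx)
        for i in idx:
            assignment[i] = pointer % n_folds
            pointer += 1
    return CVPlan(
        n_folds=n_folds, seed=seed, fold_assignment=assignment, stratified=True
    )


def accuracy(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean 0-1 gain: fraction of samples whose predicted class is correct."""
    y = np.asarray(y, dtype=object)
    yhat = np.asarray(yhat, dtype=object)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch between truth and predictions")
    return float(np.mean(y == yhat))


def class_metrics(
    y: np.ndarray, yhat: np.ndarray, class_names: list[str]
) -> EvaluationReport:
    """Per-class accuracies, their geometric mean, and the confusion matrix.

    The geometric mean ``(prod_k acc_k)^(1/n_c)`` is imbalance-robust: a
    classifier that shunts every cell into the majority class keeps a high
    plain accuracy but scores zero here.
    """
    y = np.asarray(y, dtype=object)
    yhat = np.asarray(yhat, dtype=object)
    unknown = set(y) - set(class_names)
    if unknown:
        raise ValueError(f"labels outside class_names: {sorted(unknown)}")
    n_c = len(class_names)
    confusion = np.zeros((n_c, n_c), dtype=int)
    index = {c: i for i, c in enumerate(class_names)}
    for t, p in zip(y, yhat):
        confusion[index[t], index.get(p, -1)] += 1
    class_acc = {}
    for i, c in enumerate(class_names):
        total = confusion[i].sum()
        class_acc[c] = float(confusion[i, i] / total) if total else float("nan")
    present = [c for i, c in enumerate(class_names) if confusion[i].sum()]
    gmean = float(
        np.prod([class_acc[c] for c in present]) ** (1.0 / len(present))
    )
    return EvaluationReport(
        class_names=list(class_names),
        accuracy=accuracy(y, yhat),
        class_accuracies=class_acc,
        geometric_mean=gmean,
        confusion=confusion,
    )


def _resolve_n_fs(value, n: int) -> int:
    if value == "all":
        return n
    return min(int(value), n)


def _spec_from_candidate(candidate: dict, space: SearchSpace) -> ClassifierSpec:
    return ClassifierSpec(
        method=space.classifier,
        k=int(candidate.get("k", 5)),
        C=float(candidate.get("C", 1.0)),
        gamma=float(candidate.get("gamma", 0.1)),
        landmarks=int(candidate.get("landmarks", 100)),
        priors=space.priors,
        seed=space.seed,
    )


def fit_candidate(
    train: FeatureTable,
    candidate: dict,
    space: SearchSpace,
    ranking: FilterRanking | None = None,
) -> TrainedModel:
    """Fit scaler, filter ranking and classifier for one candidate.

    ``ranking`` may be supplied to reuse a pre-computed ranking (global-
    ranking mode); otherwise it is computed from ``train`` alone.
    """
    scaler = fit_scaler(train, space.scaling)
    scaled = apply_scaler(train, scaler)
    if ranking is None:
        ranking = rank_features(scaled, space.filter_method, space.n_bins)
    n_fs = _resolve_n_fs(candidate["n_fs"], train.n)
    idx = select_top(ranking, n_fs)
    spec = _spec_from_candidate(candidate, space)
    model = train_classifier(
        scaled.values[:, idx], scaled.labels, spec, list(scaled.class_names)
    )
    model.scaler = scaler
    model.feature_indices = idx
    model.feature_names = [train.feature_names[i] for i in idx]
    return model


def cross_validate(
    candidate: dict,
    d_ms: FeatureTable,
    plan: CVPlan,
    space: SearchSpace,
    metric: str = "accuracy",
    global_ranking: FilterRanking | None = None,
) -> tuple[float, list[float]]:
    """Mean and per-fold validation metric for one candidate.

    Scaler and (by default) filter ranking are refitted inside every fold
    on the training subsets only.  ``global_ranking`` short-circuits the
    per-fold ranking when the space requests ranking once on all of
    ``D_MS`` (the style used for feature-count sweeps).
    """
    if d_ms.labels is None:
        raise ValueError("cross-validation requires labels")
    if metric not in ("accuracy", "geometric_mean"):
        raise ValueError("metric must be 'accuracy' or 'geometric_mean'")
    fold_scores = []
    for fold in range(plan.n_folds):
        train_idx, val_idx = plan.split(fold)
        train = d_ms.take_rows(train_idx)
        val = d_ms.take_rows(val_idx)
        model = fit_candidate(train, candidate, space, ranking=global_ranking)
        yhat = predict(model, val)
        if metric == "accuracy":
            fold_scores.append(accuracy(val.labels, yhat))
        else:
            fold_scores.append(
                class_metrics(val.labels, yhat, d_ms.class_names).geometric_mean
            )
    return float(np.mean(fold_scores)), fold_scores


def _tie_key(candidate: dict, position: int) -> tuple:
    """Sort key for winners: fewer features, then smaller k/C/gamma, then order."""
    n_fs = candidate["n_fs"]
    n_fs_key = np.inf if n_fs == "all" else int(n_fs)
    return (
        n_fs_key,
        candidate.get("k", 0),
        candidate.get("C", 0.0),
        candidate.get("gamma", 0.0),
        position,
    )


def _maybe_warn_imbalance(table: FeatureTable, metric: str) -> None:
    counts = list(table.class_counts().values())
    if metric == "accuracy" and max(counts) / max(min(counts), 1) > _IMBALANCE_WARN_RATIO:
        logger.warning(
            "class ratio exceeds 1:%d; consider metric='geometric_mean' "
            "for imbalance-robust selection",
            int(_IMBALANCE_WARN_RATIO),
        )


def _run_search(
    candidates: list[dict],
    d_ms: FeatureTable,
    plan: CVPlan,
    space: SearchSpace,
    metric: str,
    test: FeatureTable | None,
) -> ModelSelectionResult:
    _maybe_warn_imbalance(d_ms, metric)
    global_ranking = None
    if not space.per_fold_ranking:
        scaled = apply_scaler(d_ms, fit_scaler(d_ms, space.scaling))
        global_ranking = rank_features(scaled, space.filter_method, space.n_bins)

    evaluated = []
    for pos, cand in enumerate(candidates):
        mean_score, fold_scores = cross_validate(
            cand, d_ms, plan, space, metric, global_ranking
        )
        evaluated.append(
            {
                **cand,
                "mean_cv_metric": mean_score,
                "fold_metrics": fold_scores,
                "_position": pos,
            }
        )
    best_score = max(e["mean_cv_metric"] for e in evaluated)
    contenders = [e for e in evaluated if e["mean_cv_metric"] == best_score]
    winner = min(contenders, key=lambda e: _tie_key(e, e["_position"]))

    final_model = fit_candidate(
        d_ms, winner, space, ranking=global_ranking
    )
    test_report = None
    if test is not None and test.m:
        yhat = predict(final_model, test)
        test_report = class_metrics(test.labels, yhat, d_ms.class_names)
    for e in evaluated:
        e.pop("_position")
    return ModelSelectionResult(
        candidates=evaluated,
        winner={k: v for k, v in winner.items() if k != "_position"},
        model=final_model,
        ranking=global_ranking,
        test_report=test_report,
    )


def grid_search(
    space: SearchSpace,
    d_ms: FeatureTable,
    plan: CVPlan,
    metric: str = "accuracy",
    test: FeatureTable | None = None,
) -> ModelSelectionResult:
    """Exhaustive search over the Cartesian product of applicable grids.

    The winner maximizes the mean CV metric; exact ties favor simpler
    models (fewer features, then smaller k/C/gamma, then grid order).
    The winning settings are refitted on all of ``D_MS`` and, when a test
    table is supplied, scored once on it.
    """
    names = space.candidate_params()
    grids = [space.grid(nm) for nm in names]
    if any(not g for g in grids):
        raise ValueError("empty grid in search space")
    candidates = [dict(zip(names, combo)) for combo in itertools.product(*grids)]
    return _run_search(candidates, d_ms, plan, space, metric, test)


def random_search(
    space: SearchSpace,
    n_draws: int,
    seed: int,
    d_ms: FeatureTable,
    plan: CVPlan,
    metric: str = "accuracy",
    test: FeatureTable | None = None,
) -> ModelSelectionResult:
    """Random candidate sampling with the same winner/refit/test contract.

    Discrete grids are sampled uniformly; ``C`` and ``gamma`` are drawn
    log-uniformly between the extremes of their grids.  Deterministic per
    seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    names = space.candidate_params()
    candidates = []
    for _ in range(n_draws):
        cand: dict[str, Any] = {}
        for nm in names:
            grid = space.grid(nm)
            if nm in ("C", "gamma") and len(grid) > 1:
                lo, hi = np.log(min(grid)), np.log(max(grid))
                cand[nm] = float(np.exp(rng.uniform(lo, hi)))
            else:
                cand[nm] = grid[int(rng.integers(len(grid)))]
        candidates.append(cand)
    return _run_search(candidates, d_ms, plan, space, metric, test)
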