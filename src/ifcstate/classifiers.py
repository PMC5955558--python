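"""Classifiers for cell-state prediction.

Four schemes of increasing complexity, matching common practice for
imaging-flow-cytometry feature tables:

* **LDA / QDA** — Gaussian class-conditional models.  The class label of
  a query ``x`` is the maximizer of the posterior ``P(c_k | x)``; with
  equal priors (the default, appropriate when the deployment class
  frequencies are unknown) this reduces to maximizing the class
  likelihood.  LDA pools one covariance across classes (linear decision
  boundary), QDA fits one per class (quadratic boundary).
* **KNN** — majority vote among the ``k`` Euclidean nearest training
  cells; assumption-free but sensitive to class imbalance for large
  ``k``.
* **LLSVM** — low-rank linearized SVM: a Gaussian-kernel SVM made
  tractable by approximating the kernel feature map with a Nyström
  decomposition over k-means landmarks, then training a plain linear
  soft-margin SVM ``f(x) = sgn(w . z(x) + b)`` in the mapped space.

The module-level :func:`train_classifier` / :func:`predict` pair adds the
bookkeeping every scheme shares: the fitted scaler and the selected
feature subset travel with the model so that prediction applies exactly
the training-time transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.spatial.distance import cdist

from .feature_table import FeatureTable
from .preprocessing import ScalingParams, apply_scaler

__all__ = [
    "ClassifierSpec",
    "TrainedModel",
    "train_lda",
    "train_qda",
    "predict_discriminant",
    "train_knn",
    "predict_knn",
    "gaussian_kernel",
    "kmeans_landmarks",
    "nystrom_map",
    "train_linear_svm",
    "linear_svm_objective",
    "train_llsvm",
    "predict_llsvm",
    "train_classifier",
    "predict",
    "predict_proba",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

#: condition-number threshold beyond which a covariance is ridged
_COND_LIMIT = 1e8
_RIDGE_EPS = 1e-6


@dataclass
class ClassifierSpec:
    """Hyperparameters of one classifier candidate."""

    method: str  # LDA | QDA | KNN | LLSVM
    k: int = 5
    C: float = 1.0
    gamma: float = 0.1
    landmarks: int = 100
    priors: str = "equal"  # equal | empirical
    seed: int = 0

    def __post_init__(self) -> None:
        self.method = self.method.upper()
        if self.method not in ("LDA", "QDA", "KNN", "LLSVM"):
            raise ValueError(f"unknown classifier method: {self.method}")
        if self.priors not in ("equal", "empirical"):
            raise ValueError("priors must be 'equal' or 'empirical'")
        if self.method == "KNN" and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.method == "LLSVM":
            if self.C <= 0:
                raise ValueError("C must be > 0")
            if self.gamma <= 0:
                raise ValueError("gamma must be > 0")
            if self.landmarks < 1:
                raise ValueError("landmark count must be >= 1")


@dataclass
class TrainedModel:
    """A fitted classifier plus the transform it was trained behind.

    ``params`` holds method-specific numeric parameters (means and
    covariance factors, the stored training set, or the Nyström map and
    linear weights).  ``scaler`` and ``feature_indices`` record the
    training-time preprocessing; :func:`predict` replays both.
    """

    method: str
    class_names: list[str]
    params: dict[str, Any]
    scaler: ScalingParams | None = None
    feature_indices: list[int] | None = None
    feature_names: list[str] | None = None  # names of the selected features
    spec: ClassifierSpec | None = None

    @property
    def n_features(self) -> int:
        return int(self.params["n_features"])


# ---------------------------------------------------------------------------
# discriminant analysis
# ---------------------------------------------------------------------------


def _class_partition(y: np.ndarray, class_names: list[str]) -> list[np.ndarray]:
    return [np.nonzero(np.asarray(y, dtype=object) == c)[0] for c in class_names]


def _log_priors(counts: np.ndarray, mode: str) -> np.ndarray:
    if mode == "equal":
        return np.full(len(counts), -np.log(len(counts)))
    return np.log(counts / counts.sum())


def _maybe_ridge(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    eigvals = np.linalg.eigvalsh(cov)
    lo, hi = eigvals[0], eigvals[-1]
    if lo <= 0 or hi / max(lo, 1e-300) > _COND_LIMIT:
        cov = cov + np.eye(d) * (_RIDGE_EPS * np.trace(cov) / d)
    return cov


def _chol_or_raise(cov: np.ndarray, what: str):
    try:
        return cho_factor(_maybe_ridge(cov), lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"{what} covariance singular even after regularization"
        ) from exc


def train_lda(
    X: np.ndarray,
    y: np.ndarray,
    priors: str = "equal",
    class_names: list[str] | None = None,
) -> TrainedModel:
    """Fit linear discriminant analysis (pooled covariance).

    The pooled covariance uses denominator ``m - n_c``; a small ridge
    proportional to the mean diagonal is added when the matrix is
    ill-conditioned (near-duplicate features are common in IFC exports).
    """
    X = np.asarray(X, dtype=float)
    if class_names is None:
        class_names = list(dict.fromkeys(np.asarray(y, dtype=object)))
    parts = _class_partition(y, class_names)
    m, d = X.shape
    counts = np.array([len(p) for p in parts], dtype=float)
    for c, p in zip(class_names, parts):
        if len(p) < 2:
            raise ValueError(f"class '{c}' has fewer than 2 training samples")
    means = np.vstack([X[p].mean(axis=0) for p in parts])
    pooled = np.zeros((d, d))
    for mu_k, p in zip(means, parts):
        R = X[p] - mu_k
        pooled += R.T @ R
    pooled /= m - len(class_names)
    factor = _chol_or_raise(pooled, "pooled")
    logdet = 2.0 * np.sum(np.log(np.diag(factor[0])))
    return TrainedModel(
        method="LDA",
        class_names=list(class_names),
        params={
            "n_features": d,
            "means": means,
            "covariance": pooled,
            "log_det": logdet,
            "log_priors": _log_priors(counts, priors),
        },
    )


def train_qda(
    X: np.ndarray,
    y: np.ndarray,
    priors: str = "equal",
    class_names: list[str] | None = None,
) -> TrainedModel:
    """Fit quadratic discriminant analysis (per-class covariances, ddof=1)."""
    X = np.asarray(X, dtype=float)
    if class_names is None:
        class_names = list(dict.fromkeys(np.asarray(y, dtype=object)))
    parts = _class_partition(y, class_names)
    d = X.shape[1]
    counts = np.array([len(p) for p in parts], dtype=float)
    means, covs, logdets = [], [], []
    for c, p in zip(class_names, parts):
        if len(p) < 2:
            raise ValueError(f"class '{c}' has fewer than 2 training samples")
        mu = X[p].mean(axis=0)
        R = X[p] - mu
        cov = _maybe_ridge(R.T @ R / (len(p) - 1))
        factor = _chol_or_raise(cov, f"class '{c}'")
        means.append(mu)
        covs.append(cov)
        logdets.append(2.0 * np.sum(np.log(np.diag(factor[0]))))
    return TrainedModel(
        method="QDA",
        class_names=list(class_names),
        params={
            "n_features": d,
            "means": np.vstack(means),
            "covariances": np.stack(covs),
            "log_dets": np.array(logdets),
            "log_priors": _log_priors(counts, priors),
        },
    )


def _discriminant_log_joint(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Log P(x | c_k) + log P(c_k) for each query row and class."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = model.params
    d = model.n_features
    if X.shape[1] != d:
        raise ValueError(f"query has {X.shape[1]} features, model expects {d}")
    const = -0.5 * d * np.log(2.0 * np.pi)
    out = np.empty((X.shape[0], len(model.class_names)))
    if model.method == "LDA":
        factor = cho_factor(p["covariance"], lower=True)
        for k, mu in enumerate(p["means"]):
            R = X - mu
            maha = np.sum(R * cho_solve(factor, R.T).T, axis=1)
            out[:, k] = const - 0.5 * (p["log_det"] + maha) + p["log_priors"][k]
    else:
        for k, mu in enumerate(p["means"]):
            factor = cho_factor(p["covariances"][k], lower=True)
            R = X - mu
            maha = np.sum(R * cho_solve(factor, R.T).T, axis=1)
            out[:, k] = const - 0.5 * (p["log_dets"][k] + maha) + p["log_priors"][k]
    return out


def predict_discriminant(
    model: TrainedModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and normalized posterior probabilities for LDA/QDA queries.

    Evaluation is in log space (stable under density underflow); posterior
    rows sum to one and argmax ties resolve to the earlier class.
    """
    if model.method not in ("LDA", "QDA"):
        raise ValueError("predict_discriminant requires an LDA or QDA model")
    lj = _discriminant_log_joint(model, X)
    shifted = lj - lj.max(axis=1, keepdims=True)
    post = np.exp(shifted)
    post /= post.sum(axis=1, keepdims=True)
    labels = np.array(
        [model.class_names[i] for i in np.argmax(lj, axis=1)], dtype=object
    )
    return labels, post


# ---------------------------------------------------------------------------
# k-nearest neighbors
# ---------------------------------------------------------------------------


def train_knn(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    class_names: list[str] | None = None,
) -> TrainedModel:
    """Store the training set for Euclidean k-nearest-neighbor voting."""
    X = np.asarray(X, dtype=float)
    if class_names is None:
        class_names = list(dict.fromkeys(np.asarray(y, dtype=object)))
    if not 1 <= k <= X.shape[0]:
        raise ValueError(f"k must be in 1..{X.shape[0]}, got {k}")
    codes = np.array(
        [class_names.index(lab) for lab in np.asarray(y, dtype=object)]
    )
    return TrainedModel(
        method="KNN",
        class_names=list(class_names),
        params={"n_features": X.shape[1], "X": X.copy(), "codes": codes, "k": k},
    )


def predict_knn(model: TrainedModel, Xq: np.ndarray) -> np.ndarray:
    """Majority class among the k nearest training rows of each query.

    Equal distances at the k-th neighbor are resolved by stable training
    row order; a tied vote goes to the class of the nearest neighbor that
    belongs to a tied class.  Fully deterministic.
    """
    if model.method != "KNN":
        raise ValueError("predict_knn requires a KNN model")
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    p = model.params
    if Xq.shape[1] != model.n_features:
        raise ValueError("query feature count mismatch")
    k = int(p["k"])
    n_c = len(model.class_names)
    D = cdist(Xq, p["X"], metric="euclidean")
    # stable argsort: equal distances keep training-row order
    nn = np.argsort(D, axis=1, kind="stable")[:, :k]
    votes = p["codes"][nn]  # (q, k) class codes ordered near -> far
    out = np.empty(Xq.shape[0], dtype=object)
    for i, row in enumerate(votes):
        counts = np.bincount(row, minlength=n_c)
        top = counts.max()
        tied = np.nonzero(counts == top)[0]
        if len(tied) == 1:
            code = tied[0]
        else:
            code = next(c for c in row if c in set(tied))
        out[i] = model.class_names[int(code)]
    return out


# ---------------------------------------------------------------------------
# low-rank linearized Gaussian-kernel SVM
# ---------------------------------------------------------------------------


def gaussian_kernel(u: np.ndarray, v: np.ndarray, gamma: float) -> float:
    """Gaussian (RBF) kernel value ``exp(-gamma * ||u - v||^2)``."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    diff = np.asarray(u, dtype=float) - np.asarray(v, dtype=float)
    return float(np.exp(-gamma * np.dot(diff, diff)))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    return np.exp(-gamma * cdist(A, B, metric="sqeuclidean"))


def kmeans_landmarks(X: np.ndarray, p: int, seed: int = 0) -> np.ndarray:
    """k-means cluster centers used as Nyström landmarks.

    Lloyd iterations from k-means++ seeding until the assignment reaches a
    fixpoint (cap 300 iterations); an emptied cluster is re-seeded from
    the point farthest from its current center.  Deterministic per seed.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    if not 1 <= p <= m:
        raise ValueError(f"landmark count must be in 1..{m}")
    rng = np.random.default_rng(seed)

    # k-means++ initialization
    chosen = [int(rng.integers(m))]
    d2 = cdist(X, X[chosen[-1:]], "sqeuclidean").ravel()
    while len(chosen) < p:
        total = d2.sum()
        if total <= 0:  # remaining points coincide with chosen centers
            pool = np.setdiff1d(np.arange(m), chosen)
            chosen.extend(pool[: p - len(chosen)].tolist())
            break
        nxt = int(rng.choice(m, p=d2 / total))
        chosen.append(nxt)
        d2 = np.minimum(d2, cdist(X, X[nxt : nxt + 1], "sqeuclidean").ravel())
    centers = X[np.array(chosen)].copy()

    assign = np.full(m, -1)
    for _ in range(300):
        D = cdist(X, centers, "sqeuclidean")
        new_assign = np.argmin(D, axis=1)
        for j in range(p):
            members = new_assign == j
            if members.any():
                centers[j] = X[members].mean(axis=0)
            else:
                farthest = int(np.argmax(D[np.arange(m), new_assign]))
                centers[j] = X[farthest]
                new_assign[farthest] = j
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    return centers


def nystrom_map(
    X: np.ndarray,
    landmarks: np.ndarray,
    gamma: float,
    eig_tol: float = 1e-10,
) -> np.ndarray:
    """Nyström feature map of ``X`` w.r.t. a landmark set.

    With ``W`` the kernel matrix among landmarks and ``W = U L U^T`` its
    eigendecomposition truncated at eigenvalues <= ``eig_tol * l_max``,
    the map is ``z(x) = L^{-1/2} U^T k(x, landmarks)``; inner products of
    mapped points reproduce the Nyström kernel approximation, exactly so
    when the landmarks are the training points themselves.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    landmarks = np.atleast_2d(np.asarray(landmarks, dtype=float))
    if landmarks.shape[0] == 0:
        raise ValueError("landmark set is empty")
    W = _kernel_matrix(landmarks, landmarks, gamma)
    eigvals, eigvecs = eigh(W)
    keep = eigvals > eig_tol * eigvals[-1]
    if not keep.any():
        raise np.linalg.LinAlgError("all landmark-kernel eigenvalues below tolerance")
    U = eigvecs[:, keep]
    lam = eigvals[keep]
    K = _kernel_matrix(X, landmarks, gamma)
    return K @ U / np.sqrt(lam)


def linear_svm_objective(
    Z: np.ndarray, y: np.ndarray, w: np.ndarray, b: float, C: float
) -> float:
    """Primal soft-margin objective ``0.5 ||w||^2 + C sum hinge``."""
    margins = 1.0 - y * (Z @ w + b)
    return float(0.5 * np.dot(w, w) + C * np.sum(np.maximum(margins, 0.0)))


def train_linear_svm(
    Z: np.ndarray,
    y: np.ndarray,
    C: float,
    tol: float = 1e-6,
    max_iter: int = 200_000,
) -> tuple[np.ndarray, float]:
    """Soft-margin linear SVM by SMO on the dual problem.

    Minimizes ``0.5 ||w||^2 + C sum_i max(0, 1 - y_i (w.z_i + b))`` for
    ``y`` in {-1, +1}.  The dual is solved with maximal-violating-pair
    working-set selection; the linear kernel lets the weight vector and
    decision values be maintained incrementally, so each iteration costs
    two matrix-vector products.  Deterministic.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float)
    m = Z.shape[0]
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("labels must contain both -1 and +1")
    if C <= 0:
        raise ValueError("C must be > 0")

    alpha = np.zeros(m)
    w = np.zeros(Z.shape[1])
    f = np.zeros(m)  # decision values w . z_i (without offset)
    diag = np.einsum("ij,ij->i", Z, Z)

    for _ in range(max_iter):
        neg_grad = y - f  # -y_t * dual gradient
        up = ((y > 0) & (alpha < C)) | ((y < 0) & (alpha > 0))
        low = ((y < 0) & (alpha < C)) | ((y > 0) & (alpha > 0))
        up_idx = np.nonzero(up)[0]
        low_idx = np.nonzero(low)[0]
        i = up_idx[int(np.argmax(neg_grad[up_idx]))]
        if neg_grad[i] - neg_grad[low_idx].min() < tol:
            break
        # second-order working-set selection: largest guaranteed decrease
        Ki = Z @ Z[i]
        b_vec = neg_grad[i] - neg_grad[low_idx]
        viable = b_vec > 0
        a_vec = np.maximum(diag[i] + diag[low_idx] - 2.0 * Ki[low_idx], 1e-12)
        gains = np.where(viable, b_vec**2 / a_vec, -np.inf)
        j = low_idx[int(np.argmax(gains))]

        s = y[i] * y[j]
        if s < 0:
            L = max(0.0, alpha[j] - alpha[i])
            H = min(C, C + alpha[j] - alpha[i])
        else:
            L = max(0.0, alpha[i] + alpha[j] - C)
            H = min(C, alpha[i] + alpha[j])
        eta = max(diag[i] + diag[j] - 2.0 * float(Ki[j]), 1e-12)
        # E_i - E_j with the (irrelevant) offset cancelling
        aj_new = alpha[j] + y[j] * ((f[i] - y[i]) - (f[j] - y[j])) / eta
        aj_new = min(max(aj_new, L), H)
        ai_new = alpha[i] + s * (alpha[j] - aj_new)

        dwi = (ai_new - alpha[i]) * y[i]
        dwj = (aj_new - alpha[j]) * y[j]
        if dwi == 0.0 and dwj == 0.0:
            break  # numerically stuck at the boundary
        w += dwi * Z[i] + dwj * Z[j]
        f += dwi * Ki + dwj * (Z @ Z[j])
        alpha[i], alpha[j] = ai_new, aj_new

    neg_grad = y - f
    free = (alpha > 1e-12) & (alpha < C - 1e-12)
    if free.any():
        b = float(np.mean(neg_grad[free]))
    else:
        up = ((y > 0) & (alpha < C)) | ((y < 0) & (alpha > 0))
        low = ((y < 0) & (alpha < C)) | ((y > 0) & (alpha > 0))
        hi = neg_grad[up].max() if up.any() else 0.0
        lo = neg_grad[low].min() if low.any() else 0.0
        b = float((hi + lo) / 2.0)
    return w, b


def train_llsvm(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    p: int | None = None,
    seed: int = 0,
    class_names: list[str] | None = None,
) -> TrainedModel:
    """Low-rank linearized Gaussian-kernel SVM (binary).

    Pipeline: k-means landmarks -> Nyström feature map -> linear SVM in
    the mapped space.  ``p`` defaults to ``min(m, 100)`` landmarks; with
    ``p = m`` the map is exact and the model coincides with a full
    Gaussian-kernel SVM up to solver tolerance.
    """
    X = np.asarray(X, dtype=float)
    if class_names is None:
        class_names = list(dict.fromkeys(np.asarray(y, dtype=object)))
    if len(class_names) != 2:
        raise ValueError("LLSVM is binary: exactly 2 classes required")
    m = X.shape[0]
    if p is None:
        p = min(m, 100)
    y_pm = np.where(np.asarray(y, dtype=object) == class_names[0], -1.0, 1.0)
    if len(set(y_pm)) < 2:
        raise ValueError("both classes must be present in training data")
    landmarks = kmeans_landmarks(X, p, seed)
    Z = nystrom_map(X, landmarks, gamma)
    w, b = train_linear_svm(Z, y_pm, C)
    W = _kernel_matrix(landmarks, landmarks, gamma)
    eigvals, eigvecs = eigh(W)
    keep = eigvals > 1e-10 * eigvals[-1]
    return TrainedModel(
        method="LLSVM",
        class_names=list(class_names),
        params={
            "n_features": X.shape[1],
            "landmarks": landmarks,
            "gamma": gamma,
            "C": C,
            "map_U": eigvecs[:, keep],
            "map_eigvals": eigvals[keep],
            "w": w,
            "b": b,
        },
    )


def predict_llsvm(model: TrainedModel, Xq: np.ndarray) -> np.ndarray:
    """Sign of the linear decision function in the Nyström-mapped space.

    A decision value of exactly zero maps to the first class, as does any
    negative value.
    """
    if model.method != "LLSVM":
        raise ValueError("predict_llsvm requires an LLSVM model")
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    p = model.params
    if Xq.shape[1] != model.n_features:
        raise ValueError("query feature count mismatch")
    K = _kernel_matrix(Xq, p["landmarks"], p["gamma"])
    Z = K @ p["map_U"] / np.sqrt(p["map_eigvals"])
    score = Z @ p["w"] + p["b"]
    return np.where(score > 0, model.class_names[1], model.class_names[0]).astype(
        object
    )


# ---------------------------------------------------------------------------
# dispatch and pipeline-aware prediction
# ---------------------------------------------------------------------------


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    class_names: list[str] | None = None,
) -> TrainedModel:
    """Train the classifier named by ``spec`` on an already-prepared matrix."""
    if spec.method == "LDA":
        model = train_lda(X, y, spec.priors, class_names)
    elif spec.method == "QDA":
        model = train_qda(X, y, spec.priors, class_names)
    elif spec.method == "KNN":
        model = train_knn(X, y, spec.k, class_names)
    else:
        model = train_llsvm(
            X,
            y,
            C=spec.C,
            gamma=spec.gamma,
            p=min(spec.landmarks, len(np.asarray(y, dtype=object))),
            seed=spec.seed,
            class_names=class_names,
        )
    model.spec = spec
    return model


def _prepare_query(model: TrainedModel, table: FeatureTable) -> np.ndarray:
    if model.scaler is not None:
        if list(table.feature_names) != list(model.scaler.feature_names):
            raise ValueError(
                "query table features do not match the model's training schema"
            )
        table = apply_scaler(table, model.scaler)
    X = table.values
    if model.feature_indices is not None:
        if model.feature_names is not None:
            got = [table.feature_names[i] for i in model.feature_indices]
            if got != list(model.feature_names):
                raise ValueError("selected feature names changed since training")
        X = X[:, model.feature_indices]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"query has {X.shape[1]} features after selection, "
            f"model expects {model.n_features}"
        )
    return X


def predict(model: TrainedModel, table: FeatureTable) -> np.ndarray:
    """Predict class labels for a feature table.

    Applies the model's stored scaler and feature subset exactly as at
    training time, then dispatches to the method-specific predictor.
    """
    X = _prepare_query(model, table)
    if model.method in ("LDA", "QDA"):
        labels, _ = predict_discriminant(model, X)
        return labels
    if model.method == "KNN":
        return predict_knn(model, X)
    return predict_llsvm(model, X)


def predict_proba(model: TrainedModel, table: FeatureTable) -> np.ndarray | None:
    """Posterior probabilities where the method defines them (LDA/QDA)."""
    if model.method not in ("LDA", "QDA"):
        return None
    X = _prepare_query(model, table)
    _, post = predict_discriminant(model, X)
    return post


# ---------------------------------------------------------------------------
# serialization (versioned text format; full float precision)
# ---------------------------------------------------------------------------


def _encode(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _decode(obj: Any) -> Any:
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=obj["dtype"])
        return {k: _decode(v) for k, v in obj.items()}
    return obj


def save_model(model: TrainedModel, path: str) -> None:
    """Write a model as versioned JSON; floats keep full repr precision."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "method": model.method,
        "class_names": model.class_names,
        "params": _encode(model.params),
        "scaler": model.scaler.to_dict() if model.scaler else None,
        "feature_indices": model.feature_indices,
        "feature_names": model.feature_names,
        "spec": vars(model.spec) if model.spec else None,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str) -> TrainedModel:
    """Load a model saved by :func:`save_model` (bit-identical predictions)."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {doc.get('format_version')}")
    return TrainedModel(
        method=doc["method"],
        class_names=list(doc["class_names"]),
        params=_decode(doc["params"]),
        scaler=ScalingParams.from_dict(doc["scaler"]) if doc["scaler"] else None,
        feature_indices=doc["feature_indices"],
        feature_names=doc["feature_names"],
        spec=ClassifierSpec(**doc["spec"]) if doc["spec"] else None,
    )
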