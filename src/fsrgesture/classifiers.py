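"""From-scratch gesture classifiers.

Implemented in closed form / with a dedicated solver rather than through an
external learning library (external implementations serve only as
cross-check oracles in the test suite):

* LDA — Gaussian discriminant with class means, pooled within-class
  covariance and frequency priors; ridge-regularized when ill-conditioned.
* QDA — per-class covariances, otherwise as LDA.
* linear SVM — one-vs-one soft-margin machines trained by SMO on the dual
  (maximal-violating-pair working-set selection), majority vote with ties
  broken by summed decision values.
* k-NN — Euclidean metric, default k=1, ties broken by lowest class code.

A ``plugin`` kind wraps any external predict function for classifiers the
package does not implement natively (kernel SVMs, forests, networks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist

from .errors import TrainingError
from .features import GestureDatabase

#: Condition number above which covariance matrices are ridge-regularized.
_COND_LIMIT = 1e10
_RIDGE_EPS = 1e-8


@dataclass
class TrainedModel:
    """A trained classifier: kind, class codes, feature layout, parameters.

    ``params`` maps names to arrays/scalars and is losslessly serializable
    (see :mod:`fsrgesture.io`).  ``plugin_predict`` is only set for plugin
    models and is not serializable.
    """

    kind: str
    classes: np.ndarray
    feature_names: list[str]
    params: dict
    plugin_predict: Callable[[np.ndarray], np.ndarray] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return _PREDICTORS[self.kind](self, X)

    def predict_db(self, db: GestureDatabase) -> np.ndarray:
        if db.feature_names != self.feature_names:
            raise ValueError(
                f"database features {db.feature_names} do not match model "
                f"features {self.feature_names}"
            )
        return self.predict(db.X)


def _class_split(db: GestureDatabase, min_rows: int = 2):
    X, y = db.X, db.y
    if not np.all(np.isfinite(X)):
        raise TrainingError("database contains non-finite features")
    classes = np.unique(y)
    if len(classes) < 2:
        raise TrainingError("need at least two classes")
    groups = {c: X[y == c] for c in classes}
    for c, rows in groups.items():
        if len(rows) < min_rows:
            raise TrainingError(f"class {c} has {len(rows)} rows (< {min_rows})")
    return X, y, classes, groups


def _regularize(cov: np.ndarray) -> np.ndarray:
    """Add a ridge of eps*tr/d when the covariance is ill-conditioned."""
    d = cov.shape[0]
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        ridge = _RIDGE_EPS * np.trace(cov) / d
        if ridge <= 0.0:
            ridge = _RIDGE_EPS
        cov = cov + ridge * np.eye(d)
    return cov


def train_lda(db: GestureDatabase) -> TrainedModel:
    """Closed-form linear discriminant analysis.

    Discriminant score: delta_k(x) = x' S^-1 mu_k - mu_k' S^-1 mu_k / 2
    + ln pi_k, with S the pooled within-class covariance (n - K degrees of
    freedom) and pi_k the class frequencies; predict by argmax, ties to the
    lowest class code.
    """
    X, y, classes, groups = _class_split(db)
    n, d = X.shape
    means = np.stack([groups[c].mean(axis=0) for c in classes])
    scatter = sum(
        (rows - rows.mean(axis=0)).T @ (rows - rows.mean(axis=0))
        for rows in groups.values()
    )
    cov = _regularize(scatter / (n - len(classes)))
    priors = np.array([len(groups[c]) / n for c in classes])
    coef = np.linalg.solve(cov, means.T).T  # (K, d)
    intercept = -0.5 * np.einsum("kd,kd->k", means, coef) + np.log(priors)
    return TrainedModel(
        "lda",
        classes,
        db.feature_names,
        {
            "means": means,
            "covariance": cov,
            "priors": priors,
            "coef": coef,
            "intercept": intercept,
        },
    )


def _predict_lda(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    scores = X @ np.asarray(model.params["coef"]).T + np.asarray(
        model.params["intercept"]
    )
    return model.classes[np.argmax(scores, axis=1)]


def train_qda(db: GestureDatabase) -> TrainedModel:
    """Quadratic discriminant analysis with per-class sample covariances."""
    X, y, classes, groups = _class_split(db)
    n = len(X)
    means, covs = [], []
    for c in classes:
        rows = groups[c]
        means.append(rows.mean(axis=0))
        centered = rows - rows.mean(axis=0)
        covs.append(_regularize(centered.T @ centered / (len(rows) - 1)))
    priors = np.array([len(groups[c]) / n for c in classes])
    return TrainedModel(
        "qda",
        classes,
        db.feature_names,
        {"means": np.stack(means), "covariances": np.stack(covs), "priors": priors},
    )


def _predict_qda(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    means = np.asarray(model.params["means"])
    covs = np.asarray(model.params["covariances"])
    priors = np.asarray(model.params["priors"])
    scores = np.empty((len(X), len(means)))
    for k, (mu, cov, pi) in enumerate(zip(means, covs, priors)):
        sign, logdet = np.linalg.slogdet(cov)
        diff = X - mu
        maha = np.einsum("nd,nd->n", diff, np.linalg.solve(cov, diff.T).T)
        scores[:, k] = np.log(pi) - 0.5 * logdet - 0.5 * maha
    return model.classes[np.argmax(scores, axis=1)]


def train_knn(db: GestureDatabase, k: int = 1) -> TrainedModel:
    """k-nearest-neighbours (stores the training rows)."""
    X, y, classes, _ = _class_split(db, min_rows=1)
    if not 1 <= k <= len(X):
        raise TrainingError(f"k={k} out of range for {len(X)} rows")
    return TrainedModel(
        "knn", classes, db.feature_names, {"X": X, "y": y, "k": k}
    )


def _predict_knn(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    train_X = np.asarray(model.params["X"])
    train_y = np.asarray(model.params["y"])
    k = int(model.params["k"])
    dist = cdist(X, train_X)
    out = np.empty(len(X), dtype=int)
    for i, row in enumerate(dist):
        # lexsort: nearest first, distance ties resolved by lowest class code
        order = np.lexsort((train_y, row))[:k]
        votes = np.bincount(train_y[order])
        out[i] = int(np.argmax(votes))  # argmax tie -> lowest code
    return out


# --------------------------------------------------------------------------
# Linear SVM (one-vs-one, SMO dual solver)

def _smo_linear(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    tol: float = 1e-6,
    max_iter: int = 200_000,
) -> tuple[np.ndarray, float]:
    """Solve the soft-margin linear SVM dual by sequential minimal
    optimization with second-order working-set selection.

    Minimizes 0.5*a'Qa - e'a subject to y'a = 0, 0 <= a <= C, with
    Q = (y y') * (X X'); the first index is the maximal KKT violator, the
    second maximizes the second-order decrease along the pair direction.
    Returns the primal weight vector and bias.
    """
    n = len(y)
    Q = (X @ X.T) * np.outer(y, y)
    diag = np.diag(Q).copy()
    alpha = np.zeros(n)
    grad = -np.ones(n)
    m = M = 0.0
    for _ in range(max_iter):
        yg = -y * grad
        up = np.where(y > 0, alpha < C - 1e-12, alpha > 1e-12)
        low = np.where(y > 0, alpha > 1e-12, alpha < C - 1e-12)
        if not up.any() or not low.any():
            break
        i = int(np.flatnonzero(up)[np.argmax(yg[up])])
        m = yg[i]
        M = yg[low].min()
        if m - M < tol:
            break
        # second-order choice of j among sufficiently violating low-set rows
        diff = m - yg
        cand = low & (diff > 0)
        quad_all = np.maximum(diag[i] + diag - 2.0 * y[i] * y * Q[i], 1e-12)
        gain = np.where(cand, diff * diff / quad_all, -np.inf)
        j = int(np.argmax(gain))
        s = y[i] * y[j]
        quad = max(Q[i, i] + Q[j, j] - 2.0 * s * Q[i, j], 1e-12)
        t = -(grad[i] - s * grad[j]) / quad
        lo_t, hi_t = -alpha[i], C - alpha[i]
        if s > 0:
            lo_t, hi_t = max(lo_t, alpha[j] - C), min(hi_t, alpha[j])
        else:
            lo_t, hi_t = max(lo_t, -alpha[j]), min(hi_t, C - alpha[j])
        t = min(max(t, lo_t), hi_t)
        if t == 0.0:
            break
        alpha[i] += t
        alpha[j] -= s * t
        grad += (Q[:, i] - s * Q[:, j]) * t
    free = (alpha > 1e-8) & (alpha < C - 1e-8)
    if free.any():
        bias = float(np.mean((-y * grad)[free]))
    else:
        bias = float((m + M) / 2.0)
    w = (alpha * y) @ X
    return w, bias


def svm_objective(
    w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray, C: float
) -> float:
    """Primal soft-margin objective 0.5*||w||^2 + C * sum hinge."""
    margins = 1.0 - y * (X @ w + b)
    return 0.5 * float(w @ w) + C * float(np.clip(margins, 0.0, None).sum())


def train_linear_svm(
    db: GestureDatabase, C: float = 1.0, tol: float = 1e-6, seed: int | None = None
) -> TrainedModel:
    """One-vs-one soft-margin linear SVM (C=1 by default).

    One hyperplane per unordered class pair, trained by SMO; prediction by
    majority vote, ties broken by summed signed decision values, then by
    lowest class code.  The solver is deterministic; ``seed`` is accepted
    for interface uniformity and unused.
    """
    X, y, classes, groups = _class_split(db, min_rows=1)
    pairs, weights, biases = [], [], []
    for a, b in combinations(classes, 2):
        Xa, Xb = groups[a], groups[b]
        Xp = np.vstack([Xa, Xb])
        yp = np.concatenate([np.ones(len(Xa)), -np.ones(len(Xb))])
        w, bias = _smo_linear(Xp, yp, C, tol=tol)
        pairs.append((int(a), int(b)))
        weights.append(w)
        biases.append(bias)
    return TrainedModel(
        "linear_svm",
        classes,
        db.feature_names,
        {
            "pairs": np.asarray(pairs),
            "weights": np.stack(weights),
            "biases": np.asarray(biases),
            "C": C,
        },
    )


def _predict_svm(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    pairs = np.asarray(model.params["pairs"])
    weights = np.asarray(model.params["weights"])
    biases = np.asarray(model.params["biases"])
    classes = model.classes
    index = {int(c): i for i, c in enumerate(classes)}
    votes = np.zeros((len(X), len(classes)))
    scores = np.zeros((len(X), len(classes)))
    for (a, b), w, bias in zip(pairs, weights, biases):
        f = X @ w + bias  # positive -> class a
        ia, ib = index[int(a)], index[int(b)]
        votes[:, ia] += f >= 0
        votes[:, ib] += f < 0
        scores[:, ia] += f
        scores[:, ib] -= f
    # rank by (votes, summed decision value, lower code); argmax of the
    # lexicographic key keeps the lowest code on exact ties
    out = np.empty(len(X), dtype=int)
    for i in range(len(X)):
        best = max(
            range(len(classes)),
            key=lambda k: (votes[i, k], scores[i, k], -int(classes[k])),
        )
        out[i] = int(classes[best])
    return out


def _predict_plugin(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    if model.plugin_predict is None:
        raise TrainingError("plugin model has no predict function attached")
    return np.asarray(model.plugin_predict(X), dtype=int)


def plugin_model(
    predict: Callable[[np.ndarray], np.ndarray],
    classes: np.ndarray,
    feature_names: list[str],
    name: str = "plugin",
) -> TrainedModel:
    """Wrap an external classifier's predict function as a TrainedModel."""
    return TrainedModel(
        "plugin", np.asarray(classes), list(feature_names), {"name": name}, predict
    )


_PREDICTORS = {
    "lda": _predict_lda,
    "qda": _predict_qda,
    "knn": _predict_knn,
    "linear_svm": _predict_svm,
    "plugin": _predict_plugin,
}

#: Named trainer registry used by the CLI and cohort runner.
TRAINERS: dict[str, Callable[[GestureDatabase], TrainedModel]] = {
    "lda": train_lda,
    "qda": train_qda,
    "linear_svm": train_linear_svm,
    "knn": train_knn,
}
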