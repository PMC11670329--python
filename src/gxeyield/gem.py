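"""Generalized Ensemble Method (GEM): simplex-constrained least squares.

Given a matrix of base-model predictions ``P`` (n observations x k
models) and observed values ``y``, GEM finds non-negative weights
``w`` summing to one that minimize the mean squared error of the
combined prediction ``P @ w``.  The problem is a convex quadratic
program over the probability simplex; every vertex (a single base
model) is feasible, so the fitted ensemble can never be worse than the
best base model on the fitting set.

Weights are conventionally fitted on validation-set predictions and
then applied unchanged to test-set predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize


@dataclass(frozen=True)
class PredictionSet:
    """Aligned base-model predictions and observed values."""

    predictions: np.ndarray  # (n, k)
    y: np.ndarray  # (n,)
    model_ids: tuple[str, ...] = ()

    def __post_init__(self):
        P = np.asarray(self.predictions, dtype=float)
        y = np.asarray(self.y, dtype=float).ravel()
        if P.ndim == 1:
            P = P[:, None]
        if P.ndim != 2 or P.shape[0] != y.shape[0]:
            raise ValueError(f"shape mismatch: predictions {P.shape}, y {y.shape}")
        if y.size < 1 or P.shape[1] < 1:
            raise ValueError("need at least one observation and one model")
        if not (np.isfinite(P).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in prediction set")
        object.__setattr__(self, "predictions", P)
        object.__setattr__(self, "y", y)
        ids = self.model_ids or tuple(f"model_{j}" for j in range(P.shape[1]))
        if len(ids) != P.shape[1]:
            raise ValueError("model_ids length does not match prediction columns")
        object.__setattr__(self, "model_ids", tuple(ids))

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def k(self) -> int:
        return self.predictions.shape[1]


@dataclass(frozen=True)
class EnsembleWeights:
    """Fitted simplex weights and the achieved validation MSE."""

    weights: np.ndarray
    objective: float  # mean squared error at the fitted weights
    model_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float).ravel()
        if (w < -1e-9).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "weights", w)


def _mse(P: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    r = P @ w - y
    return float(np.mean(r * r))


def fit_gem(preds: PredictionSet, tolerance: float = 1e-8) -> EnsembleWeights:
    """Fit simplex-constrained least-squares ensemble weights.

    Minimizes ``mean((y - P w)^2)`` subject to ``w >= 0`` and
    ``sum(w) = 1`` with a sequential-quadratic solver started from the
    uniform weight vector, then guards the convex-program guarantee: if
    the solver ever returns a point worse than the best single model,
    the best vertex (lowest model index on ties) is returned instead.
    """
    P, y = preds.predictions, preds.y
    n, k = preds.n, preds.k
    if k == 1:
        w = np.array([1.0])
        return EnsembleWeights(w, _mse(P, y, w), preds.model_ids)

    def obj(w):
        r = P @ w - y
        return float(r @ r) / n

    def grad(w):
        return 2.0 / n * (P.T @ (P @ w - y))

    w0 = np.full(k, 1.0 / k)
    res = optimize.minimize(
        obj,
        w0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones_like(w)}],
        options={"ftol": min(tolerance, 1e-12), "maxiter": 500},
    )
    w = np.clip(res.x, 0.0, None)
    w /= w.sum()
    obj_w = _mse(P, y, w)

    # Convex-program guarantee: vertices are feasible, so the fit can
    # never be worse than the best base model on the fitting set.
    vertex_objs = [_mse(P, y, np.eye(k)[j]) for j in range(k)]
    j_best = int(np.argmin(vertex_objs))  # argmin takes the lowest index on ties
    if obj_w > vertex_objs[j_best] * (1.0 + 1e-12) + 1e-15:
        w = np.eye(k)[j_best]
        obj_w = vertex_objs[j_best]
    return EnsembleWeights(w, obj_w, preds.model_ids)


def gem_predict(weights: EnsembleWeights, predictions: np.ndarray) -> np.ndarray:
    """Row-wise weighted sum of base-model predictions."""
    P = np.asarray(predictions, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if P.shape[1] != weights.weights.shape[0]:
        raise ValueError(
            f"dimension mismatch: {P.shape[1]} prediction columns, "
            f"{weights.weights.shape[0]} weights"
        )
    return P @ weights.weights


def ensemble_predictor(models, weights: EnsembleWeights):
    """Callable combining fitted base models under the GEM weights.

    ``models`` is any sequence of objects exposing ``predict(features)``
    (e.g. :class:`~gxeyield.nets.TrainedModel`); the returned callable
    maps a feature matrix to the weighted prediction.
    """
    if len(models) != weights.weights.shape[0]:
        raise ValueError("model count does not match weight count")

    def predict(features):
        P = np.column_stack([m.predict(features) for m in models])
        return gem_predict(weights, P)

    return predict


def grid_oracle(preds: PredictionSet, resolution: int = 1000) -> EnsembleWeights:
    """Exhaustive simplex-grid search; verification oracle for small k.

    Enumerates all weight vectors with components that are multiples of
    ``1/resolution`` and returns the best.  Only intended for tests
    (k <= 3).
    """
    if preds.k > 3:
        raise ValueError("grid oracle supports at most 3 models")
    if resolution < 100:
        raise ValueError("resolution must be >= 100")
    P, y = preds.predictions, preds.y
    if preds.k == 1:
        w = np.array([1.0])
        return EnsembleWeights(w, _mse(P, y, w), preds.model_ids)
    if preds.k == 2:
        i = np.arange(resolution + 1)
        W = np.stack([i, resolution - i], axis=1) / resolution  # (m, 2)
    else:
        i, j = np.meshgrid(np.arange(resolution + 1), np.arange(resolution + 1),
                           indexing="ij")
        mask = i + j <= resolution
        W = np.stack([i[mask], j[mask], resolution - i[mask] - j[mask]],
                     axis=1) / resolution
    resid = P @ W.T - y[:, None]  # (n, m)
    objs = np.mean(resid * resid, axis=0)
    best = int(np.argmin(objs))
    return EnsembleWeights(W[best], float(objs[best]), preds.model_ids)
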