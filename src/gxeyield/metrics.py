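"""Evaluation metrics for yield prediction.

Three metrics are used throughout the package: root-mean-square error
(RMSE) and mean absolute error (MAE), both in bushels/acre, and the
Pearson correlation coefficient r between predicted and observed yield.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


def _validate(y: np.ndarray, yhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty input vectors")
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise ValueError("non-finite values in input")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root-mean-square error sqrt(mean((y - yhat)^2))."""
    y, yhat = _validate(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(y, yhat) -> float:
    """Mean absolute error mean(|y - yhat|)."""
    y, yhat = _validate(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def pearson_r(y, yhat) -> float:
    """Pearson correlation between observed and predicted values.

    Raises ``ValueError`` when either vector is constant: r is undefined
    there and returning a silent 0 would corrupt report tables.
    """
    y, yhat = _validate(y, yhat)
    yc = y - y.mean()
    pc = yhat - yhat.mean()
    denom = np.sqrt((yc ** 2).sum()) * np.sqrt((pc ** 2).sum())
    if denom == 0.0:
        raise ValueError("pearson_r undefined: at least one input is constant")
    return float((yc * pc).sum() / denom)


@dataclass(frozen=True)
class EvaluationReport:
    """Per-split metric bundle."""

    rmse: float
    mae: float
    r: float
    n: int
    split: str

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(y, yhat, split: str = "") -> EvaluationReport:
    """Compute the full metric bundle on one split."""
    y, yhat = _validate(y, yhat)
    return EvaluationReport(
        rmse=rmse(y, yhat),
        mae=mae(y, yhat),
        r=pearson_r(y, yhat),
        n=int(y.size),
        split=split,
    )
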