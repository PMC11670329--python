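"""Minibatch training of the yield regressors.

Follows the published protocol: Adam, initial learning rate 4e-4
decayed by a staircase factor of 0.96 every 2,500 steps, batch size 48,
mean-squared-error loss.  The full-scale budget is 100,000 iterations;
desk-scale runs use far fewer (the models keep learning but the point
of a reduced budget is a CPU-tractable, still-informative fit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ..preprocess import FeatureMatrix
from .layers import Adam
from .models import ArchitectureSpec, YieldRegressor, build_model


@dataclass(frozen=True)
class TrainingConfig:
    initial_lr: float = 4e-4
    decay_rate: float = 0.96
    decay_steps: int = 2500
    iterations: int = 100_000
    batch_size: int = 48
    seed: int = 0
    log_every: int = 100

    def __post_init__(self):
        if min(self.initial_lr, self.decay_steps, self.batch_size) <= 0:
            raise ValueError("lr, decay_steps and batch_size must be positive")
        if not (0.0 < self.decay_rate <= 1.0):
            raise ValueError("decay_rate must lie in (0, 1]")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")

    @classmethod
    def desk(cls, iterations: int = 3000, seed: int = 0) -> "TrainingConfig":
        """Reduced budget for single-CPU runs; schedule unchanged."""
        return cls(iterations=iterations, seed=seed)


def learning_rate_at(step: int, config: TrainingConfig) -> float:
    """Staircase schedule: lr0 * rate^(step // decay_steps)."""
    return config.initial_lr * config.decay_rate ** (step // config.decay_steps)


@dataclass
class TrainedModel:
    """A fitted regressor plus its training provenance."""

    model: YieldRegressor
    spec: ArchitectureSpec
    config: TrainingConfig
    loss_log: list[tuple[int, float, float]] = field(default_factory=list)

    def predict(self, features: FeatureMatrix,
                batch_size: int = 2048) -> np.ndarray:
        """Deterministic inference (dropout disabled), batched over rows."""
        out = np.empty(features.n_rows)
        for start in range(0, features.n_rows, batch_size):
            sl = slice(start, start + batch_size)
            soil = None if features.soil is None else features.soil[sl]
            out[sl] = self.model.forward(features.weather[sl],
                                         features.other[sl], soil)
        return out

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.model.save(directory)
        (directory / "training.json").write_text(json.dumps(asdict(self.config)))
        pd.DataFrame(self.loss_log, columns=["step", "lr", "loss"]).to_csv(
            directory / "loss_log.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        model = YieldRegressor.load(directory)
        config = TrainingConfig(**json.loads(
            (directory / "training.json").read_text()))
        log_path = directory / "loss_log.csv"
        log = []
        if log_path.exists():
            log = [tuple(r) for r in
                   pd.read_csv(log_path).itertuples(index=False)]
        return cls(model, model.spec, config, log)


def train(model: YieldRegressor, features: FeatureMatrix,
          train_mask: np.ndarray, config: TrainingConfig) -> TrainedModel:
    """Minibatch MSE training of ``model`` on the masked rows.

    Batches are sampled with replacement from the training rows under
    the config seed, so a run is bit-reproducible on one device.
    Aborts on a non-finite loss.
    """
    if features.y is None:
        raise ValueError("features carry no target values")
    rows = np.flatnonzero(np.asarray(train_mask, dtype=bool))
    if rows.size == 0:
        raise ValueError("training mask selects no rows")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.layers())
    log: list[tuple[int, float, float]] = []
    y = features.y
    for step in range(config.iterations):
        idx = rows[rng.integers(0, rows.size, size=config.batch_size)]
        soil = None if features.soil is None else features.soil[idx]
        pred = model.forward(features.weather[idx], features.other[idx],
                             soil, train=True, rng=rng)
        err = pred - y[idx]
        loss = float(np.mean(err * err))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at step {step}; "
                "check input scaling or lower the learning rate")
        for layer in model.layers():
            layer.zero_grads()
        model.backward(2.0 * err / err.size)
        lr = learning_rate_at(step, config)
        optimizer.step(lr)
        if step % config.log_every == 0 or step == config.iterations - 1:
            log.append((step, lr, loss))
    return TrainedModel(model, model.spec, config, log)


def fit(spec: ArchitectureSpec, features: FeatureMatrix,
        train_mask: np.ndarray, config: TrainingConfig,
        init_seed: int | None = None) -> TrainedModel:
    """Build and train a regressor matched to the feature widths."""
    n_soil = None if features.soil is None else features.soil.shape[1]
    model = build_model(spec, features.other.shape[1], n_soil,
                        seed=config.seed if init_seed is None else init_seed)
    return train(model, features, train_mask, config)
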