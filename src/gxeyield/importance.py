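"""Grouped permutation feature importance by RMSE change.

The importance of a group of feature columns is measured as the
increase in RMSE when the group's rows are jointly permuted (one
random row-permutation applied to all columns of the group, preserving
within-group coherence — so a one-hot block stays a valid one-hot
block) while every other column is left untouched.  A large RMSE
change means the predictor relied on the group.

Groups can be defined at variable granularity — year, location,
genotype, the seven weather variables, optionally soil — or at period
granularity, where each of a weather variable's 53 aggregation periods
forms its own single-column group (used to localize critical stretches
of the growing season).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .metrics import rmse
from .preprocess import N_PERIODS, WEATHER_VARS, FeatureMatrix

Predictor = Callable[[FeatureMatrix], np.ndarray]


@dataclass(frozen=True)
class FeatureGroup:
    """A named set of feature columns within one block of the design."""

    name: str
    block: str  # "other" | "weather" | "soil"
    columns: tuple[int, ...]  # other/soil: column ids; weather: unused
    variable: int = -1  # weather block: variable index
    periods: tuple[int, ...] = ()  # weather block: 0-based period ids


def define_groups(features: FeatureMatrix, granularity: str = "variable",
                  variables: tuple[str, ...] | None = None
                  ) -> list[FeatureGroup]:
    """Build the importance groups for a feature matrix.

    ``variable`` granularity yields year/location/genotype + the seven
    weather variables (+ soil when present).  ``period`` granularity
    yields 53 single-period groups for each requested weather variable.
    """
    if granularity == "variable":
        groups = [FeatureGroup(name, "other",
                               tuple(range(sl.start, sl.stop)))
                  for name, sl in features.registry.blocks.items()]
        for vi, var in enumerate(WEATHER_VARS):
            groups.append(FeatureGroup(var, "weather", (), vi,
                                       tuple(range(N_PERIODS))))
        if features.soil is not None:
            groups.append(FeatureGroup(
                "soil", "soil", tuple(range(features.soil.shape[1]))))
        return groups
    if granularity == "period":
        chosen = variables or WEATHER_VARS
        var_index = {v: i for i, v in enumerate(WEATHER_VARS)}
        groups = []
        for var in chosen:
            if var not in var_index:
                raise ValueError(f"unknown weather variable {var!r}")
            vi = var_index[var]
            groups += [FeatureGroup(f"{var}_p{p + 1}", "weather", (), vi, (p,))
                       for p in range(N_PERIODS)]
        return groups
    raise ValueError(f"unknown granularity {granularity!r}")


def permute_group(features: FeatureMatrix, group: FeatureGroup,
                  rng: np.random.Generator) -> FeatureMatrix:
    """Copy of ``features`` with the group's rows jointly permuted."""
    out = features.copy()
    perm = rng.permutation(features.n_rows)
    if group.block == "other":
        cols = list(group.columns)
        out.other[:, cols] = features.other[perm][:, cols]
    elif group.block == "weather":
        pidx = list(group.periods)
        out.weather[:, group.variable, pidx] = \
            features.weather[perm][:, group.variable][:, pidx]
    elif group.block == "soil":
        if features.soil is None:
            raise ValueError("feature matrix has no soil block")
        cols = list(group.columns)
        out.soil[:, cols] = features.soil[perm][:, cols]
    else:
        raise ValueError(f"unknown block {group.block!r}")
    return out


@dataclass
class ImportanceResult:
    """Baseline RMSE and per-group permuted RMSE / RMSE change."""

    baseline_rmse: float
    permuted_rmse: dict[str, float]
    rmse_change: dict[str, float] = field(default_factory=dict)
    repetitions: int = 1
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"group": g, "r0": self.baseline_rmse,
                 "rmse_perm": self.permuted_rmse[g],
                 "rmse_change": self.rmse_change[g],
                 "reps": self.repetitions, "seed": self.seed}
                for g in self.permuted_rmse]
        return pd.DataFrame(rows)


def _group_rng(seed: int, name: str, rep: int) -> np.random.Generator:
    # keyed by group name so results do not depend on evaluation order
    return np.random.default_rng([seed, zlib.crc32(name.encode()), rep])


def rmse_change(predictor: Predictor, features: FeatureMatrix,
                groups: list[FeatureGroup], repetitions: int = 10,
                seed: int = 0) -> ImportanceResult:
    """Permutation importance of each group against ``predictor``.

    The baseline RMSE r0 is computed once; each group's permuted RMSE
    is averaged over ``repetitions`` independent permutations (seeded
    per group, so results are deterministic and order-independent).
    """
    if features.y is None:
        raise ValueError("feature matrix carries no target values")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    r0 = rmse(features.y, predictor(features))
    permuted = {}
    for group in groups:
        vals = []
        for rep in range(repetitions):
            rng = _group_rng(seed, group.name, rep)
            shuffled = permute_group(features, group, rng)
            vals.append(rmse(features.y, predictor(shuffled)))
        permuted[group.name] = float(np.mean(vals))
    changes = {g: permuted[g] - r0 for g in permuted}
    return ImportanceResult(r0, permuted, changes, repetitions, seed)
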