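"""Optimal genotype-by-environment selection.

For every observed environment (a location-year pair with its shared
weather block), the fitted predictor scores every registered genotype
under that environment's weather, location and year; the top-k
genotypes (k = 10 by default) form the "optimal" set.  The report
compares the mean predicted yield of the optimal set with the mean
observed yield of the genotypes actually planted there — the gap, in
bushels/acre, estimates the headroom a better genotype choice would
have offered.  Gaps are reported signed: a negative gap (the planted
set already beats the model's picks) is recorded, not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .preprocess import (N_DAYS, WEATHER_VARS, CategoryRegistry,
                         FeatureMatrix, NormalizationStats, build_features,
                         weather_tensor)

Predictor = Callable[[FeatureMatrix], np.ndarray]


@dataclass(frozen=True)
class EnvironmentKey:
    """One observed (location, year) environment and its weather block."""

    location_id: str
    year: int
    state: str
    weather: np.ndarray  # (7, 214) daily values

    def __post_init__(self):
        w = np.asarray(self.weather, dtype=float)
        if w.shape != (len(WEATHER_VARS), N_DAYS):
            raise ValueError("environment weather must be 7 x 214")
        object.__setattr__(self, "weather", w)


def enumerate_environments(frame: pd.DataFrame) -> list[EnvironmentKey]:
    """Distinct (location, year) environments, weather-consistency checked."""
    weather = weather_tensor(frame)
    keys: dict[tuple[str, int], int] = {}
    out: list[EnvironmentKey] = []
    loc = frame["location_id"].astype(str).to_numpy()
    yr = frame["year"].astype(int).to_numpy()
    state = frame["state"].astype(str).to_numpy()
    for i in range(len(frame)):
        key = (loc[i], int(yr[i]))
        if key in keys:
            if not np.array_equal(weather[i], out[keys[key]].weather):
                raise ValueError(f"conflicting weather blocks for "
                                 f"environment {key}")
        else:
            keys[key] = len(out)
            out.append(EnvironmentKey(loc[i], int(yr[i]), state[i],
                                      weather[i]))
    return out


def _candidate_frame(env: EnvironmentKey,
                     genotypes: tuple[str, ...]) -> pd.DataFrame:
    n = len(genotypes)
    meta = pd.DataFrame({
        "year": [env.year] * n,
        "location_id": [env.location_id] * n,
        "state": [env.state] * n,
        "genotype_id": list(genotypes),
        "maturity_group": ["NA"] * n,  # carried, never featurized
        "yield": [np.nan] * n,
    })
    wcols = [f"{v}_{d}" for v in WEATHER_VARS for d in range(1, N_DAYS + 1)]
    flat = np.broadcast_to(env.weather.reshape(-1), (n, env.weather.size))
    return pd.concat([meta, pd.DataFrame(flat, columns=wcols)], axis=1)


def predict_all_genotypes(predictor: Predictor, env: EnvironmentKey,
                          registry: CategoryRegistry,
                          weather_stats: NormalizationStats,
                          soil_table: pd.DataFrame | None = None,
                          soil_stats: NormalizationStats | None = None
                          ) -> pd.Series:
    """Predicted yield of every registered genotype in one environment.

    Weather, location and year are held fixed at the environment's
    values; only the genotype one-hot block varies across rows.
    """
    frame = _candidate_frame(env, registry.genotypes)
    features = build_features(frame, registry, weather_stats=weather_stats,
                              soil_table=soil_table, soil_stats=soil_stats)
    preds = predictor(features)
    return pd.Series(preds, index=list(registry.genotypes))


def select_top_k(predictions: pd.Series, k: int = 10
                 ) -> tuple[list[str], float]:
    """Top-k genotypes by predicted yield; ties break by genotype id."""
    if k < 1 or k > len(predictions):
        raise ValueError(f"k must lie in [1, {len(predictions)}]")
    order = sorted(predictions.index, key=lambda g: (-predictions[g], g))
    top = order[:k]
    return top, float(predictions[top].mean())


@dataclass
class EnvironmentSelection:
    """Ranked candidates and the top-k pick for one environment."""

    env: EnvironmentKey
    predictions: pd.Series  # indexed by genotype, descending not required
    top_k: list[str]
    top_k_mean: float


def select_for_environments(predictor: Predictor, frame: pd.DataFrame,
                            registry: CategoryRegistry,
                            weather_stats: NormalizationStats, k: int = 10,
                            soil_table: pd.DataFrame | None = None,
                            soil_stats: NormalizationStats | None = None
                            ) -> list[EnvironmentSelection]:
    """Run top-k selection in every observed environment."""
    out = []
    for env in enumerate_environments(frame):
        preds = predict_all_genotypes(predictor, env, registry,
                                      weather_stats, soil_table, soil_stats)
        top, mean = select_top_k(preds, k)
        out.append(EnvironmentSelection(env, preds, top, mean))
    return out


def selection_gap_report(selections: list[EnvironmentSelection],
                         frame: pd.DataFrame,
                         group_by: str = "environment") -> pd.DataFrame:
    """Gap between predicted top-k mean yield and observed mean yield.

    ``environment`` grouping reports one row per (location, year);
    ``state-year`` averages each state's environments per year.
    """
    obs_loc = frame["location_id"].astype(str).to_numpy()
    obs_yr = frame["year"].astype(int).to_numpy()
    obs_y = frame["yield"].to_numpy(dtype=float)

    rows = []
    for sel in selections:
        mask = (obs_loc == sel.env.location_id) & (obs_yr == sel.env.year)
        if not mask.any():
            raise ValueError(f"no observed records for environment "
                             f"({sel.env.location_id}, {sel.env.year})")
        observed = float(np.nanmean(obs_y[mask]))
        rows.append({"location_id": sel.env.location_id,
                     "year": sel.env.year, "state": sel.env.state,
                     "top_k_genotypes": ",".join(sel.top_k),
                     "mean_pred_topk": sel.top_k_mean,
                     "mean_observed": observed,
                     "gap": sel.top_k_mean - observed})
    per_env = pd.DataFrame(rows)
    if group_by == "environment":
        report = per_env.copy()
        report.insert(0, "group", report["location_id"] + "/"
                      + report["year"].astype(str))
        report["n_environments"] = 1
        return report
    if group_by == "state-year":
        grouped = (per_env.groupby(["state", "year"], as_index=False)
                   .agg(n_environments=("gap", "size"),
                        mean_pred_topk=("mean_pred_topk", "mean"),
                        mean_observed=("mean_observed", "mean"),
                        gap=("gap", "mean")))
        grouped.insert(0, "group", grouped["state"] + "/"
                       + grouped["year"].astype(str))
        return grouped
    raise ValueError(f"unknown group_by {group_by!r}")
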