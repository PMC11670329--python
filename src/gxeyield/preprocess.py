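"""Raw trial records -> model-ready features and leakage-safe splits.

A trial record is one yield observation of a soybean genotype in one
environment (a location-year pair), carrying the full daily weather
block of the 214-day growing season (April 1 - October 31) for seven
variables.  Preprocessing performs four steps:

1. 4-day aggregation of each daily weather series (214 days -> 53
   periods; the last period absorbs the 6 trailing days),
2. z-score standardization of the aggregated weather (and optional
   soil) columns, with statistics fitted on a declared reference row
   set (training rows by default, to avoid leakage),
3. one-hot encoding of year, location and genotype against an ordered
   category registry (unseen categories encode as all-zeros),
4. a genotype-location-combination split: train/validation/test share
   no (genotype, location) combination, and every genotype is
   guaranteed present in training (repair moves combinations from
   validation/test into train where needed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

WEATHER_VARS = ("ADNI", "AP", "ARH", "MDNI", "MaxSur", "MinSur", "AvgSur")
N_DAYS = 214
N_PERIODS = 53
_FULL_PERIODS = 52  # 4-day periods; period 53 averages the trailing 6 days

SOIL_PROPERTIES = ("bdod", "cec", "cfvo", "clay", "nitrogen", "ocd",
                   "ocs", "phh2o", "sand", "silt", "soc")
SOIL_DEPTHS = ("0-5", "5-15", "15-30", "30-60", "60-100", "100-200")
SOIL_COLUMNS = tuple(f"{p}_{d}" for p in SOIL_PROPERTIES for d in SOIL_DEPTHS)

META_COLUMNS = ("year", "location_id", "state", "genotype_id",
                "maturity_group", "yield")
WEATHER_COLUMNS = tuple(f"{v}_{d}" for v in WEATHER_VARS
                        for d in range(1, N_DAYS + 1))


@dataclass
class TrialRecord:
    """One yield observation with its daily weather block (7 x 214)."""

    year: int
    location_id: str
    state: str
    genotype_id: str
    maturity_group: str
    yield_value: float | None
    weather: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weather, dtype=float)
        if w.shape != (len(WEATHER_VARS), N_DAYS):
            raise ValueError(f"weather block must be 7 x {N_DAYS}, got {w.shape}")
        if np.isnan(w).any():
            raise ValueError("weather block contains missing values")
        if self.yield_value is not None and self.yield_value < 0:
            raise ValueError("yield must be non-negative")
        self.weather = w


# ---------------------------------------------------------------------------
# canonical wide CSV

def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"year": r.year, "location_id": r.location_id, "state": r.state,
               "genotype_id": r.genotype_id, "maturity_group": r.maturity_group,
               "yield": np.nan if r.yield_value is None else r.yield_value}
        for vi, v in enumerate(WEATHER_VARS):
            for d in range(N_DAYS):
                row[f"{v}_{d + 1}"] = r.weather[vi, d]
        rows.append(row)
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(WEATHER_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    weather = weather_tensor(frame)
    out = []
    for i, (_, row) in enumerate(frame.iterrows()):
        y = row["yield"]
        out.append(TrialRecord(
            year=int(row["year"]), location_id=str(row["location_id"]),
            state=str(row["state"]), genotype_id=str(row["genotype_id"]),
            maturity_group=str(row["maturity_group"]),
            yield_value=None if pd.isna(y) else float(y),
            weather=weather[i]))
    return out


def write_trials_csv(frame: pd.DataFrame, path: str | Path) -> None:
    _check_trial_frame(frame)
    frame.to_csv(path, index=False)


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"location_id": str, "genotype_id": str,
                                     "state": str, "maturity_group": str})
    _check_trial_frame(frame)
    return frame


def _check_trial_frame(frame: pd.DataFrame) -> None:
    missing = [c for c in META_COLUMNS + WEATHER_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial table missing {len(missing)} columns, "
                         f"first: {missing[:4]}")
    w = frame[list(WEATHER_COLUMNS)].to_numpy(dtype=float)
    if np.isnan(w).any():
        raise ValueError("weather columns contain missing values")


def weather_tensor(frame: pd.DataFrame) -> np.ndarray:
    """Daily weather as an (n, 7, 214) array in canonical variable order."""
    w = frame[list(WEATHER_COLUMNS)].to_numpy(dtype=float)
    return w.reshape(len(frame), len(WEATHER_VARS), N_DAYS)


# ---------------------------------------------------------------------------
# weather aggregation

def aggregate_weather(daily: np.ndarray) -> np.ndarray:
    """Average a daily series into 53 periods (52 x 4 days + 1 x 6 days).

    Accepts a single 214-long series or any array whose last axis has
    length 214; aggregation applies along the last axis.
    """
    daily = np.asarray(daily, dtype=float)
    if daily.shape[-1] != N_DAYS:
        raise ValueError(f"expected {N_DAYS} daily values on the last axis, "
                         f"got {daily.shape[-1]}")
    head = daily[..., : _FULL_PERIODS * 4]
    head = head.reshape(*daily.shape[:-1], _FULL_PERIODS, 4).mean(axis=-1)
    tail = daily[..., _FULL_PERIODS * 4:].mean(axis=-1, keepdims=True)
    return np.concatenate([head, tail], axis=-1)


# ---------------------------------------------------------------------------
# normalization

@dataclass
class NormalizationStats:
    """Per-column mean/sd (population convention) on a reference row set.

    Columns with zero variance are flagged; standardizing maps them to 0.
    """

    mean: np.ndarray
    sd: np.ndarray
    columns: tuple[str, ...]

    @property
    def zero_variance(self) -> np.ndarray:
        return self.sd == 0.0

    def to_json(self) -> str:
        return json.dumps({"columns": list(self.columns),
                           "mean": self.mean.tolist(),
                           "sd": self.sd.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "NormalizationStats":
        d = json.loads(text)
        return cls(np.asarray(d["mean"], float), np.asarray(d["sd"], float),
                   tuple(d["columns"]))


def fit_normalization(values: np.ndarray, reference_mask: np.ndarray | None = None,
                      columns: tuple[str, ...] | None = None) -> NormalizationStats:
    """Fit per-column mean and population sd over the reference rows."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D column matrix")
    if reference_mask is None:
        ref = values
    else:
        reference_mask = np.asarray(reference_mask, dtype=bool)
        if reference_mask.shape[0] != values.shape[0]:
            raise ValueError("reference mask length does not match rows")
        ref = values[reference_mask]
    if ref.shape[0] < 2:
        raise ValueError("reference set must contain at least 2 rows")
    cols = columns or tuple(f"col_{j}" for j in range(values.shape[1]))
    if len(cols) != values.shape[1]:
        raise ValueError("column name count does not match matrix")
    return NormalizationStats(ref.mean(axis=0), ref.std(axis=0, ddof=0), tuple(cols))


def apply_normalization(values: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Standardize columns: (w - mean) / sd; zero-variance columns -> 0."""
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != stats.mean.shape[0]:
        raise ValueError(f"column mismatch: {values.shape[-1]} values vs "
                         f"{stats.mean.shape[0]} fitted columns")
    sd = np.where(stats.sd == 0.0, 1.0, stats.sd)
    out = (values - stats.mean) / sd
    if stats.zero_variance.any():
        out[..., stats.zero_variance] = 0.0
    return out


# ---------------------------------------------------------------------------
# one-hot encoding

@dataclass(frozen=True)
class CategoryRegistry:
    """Ordered category lists for year, location and genotype.

    Column order inside each block follows the registry order; a record
    whose category is not registered encodes as all-zeros in that block.
    """

    years: tuple[int, ...]
    locations: tuple[str, ...]
    genotypes: tuple[str, ...]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CategoryRegistry":
        return cls(tuple(sorted(frame["year"].unique().tolist())),
                   tuple(sorted(frame["location_id"].astype(str).unique())),
                   tuple(sorted(frame["genotype_id"].astype(str).unique())))

    @property
    def n_columns(self) -> int:
        return len(self.years) + len(self.locations) + len(self.genotypes)

    @property
    def blocks(self) -> dict[str, slice]:
        ny, nl = len(self.years), len(self.locations)
        return {"year": slice(0, ny),
                "location": slice(ny, ny + nl),
                "genotype": slice(ny + nl, self.n_columns)}

    def to_json(self) -> str:
        return json.dumps({"years": list(self.years),
                           "locations": list(self.locations),
                           "genotypes": list(self.genotypes)})

    @classmethod
    def from_json(cls, text: str) -> "CategoryRegistry":
        d = json.loads(text)
        return cls(tuple(d["years"]), tuple(d["locations"]), tuple(d["genotypes"]))


def _one_hot_block(values, categories) -> np.ndarray:
    index = {c: i for i, c in enumerate(categories)}
    out = np.zeros((len(values), len(categories)), dtype=np.float32)
    for i, v in enumerate(values):
        j = index.get(v)
        if j is not None:
            out[i, j] = 1.0
    return out


def one_hot_encode(frame: pd.DataFrame, registry: CategoryRegistry) -> np.ndarray:
    """Binary year/location/genotype blocks in registry order."""
    return np.concatenate([
        _one_hot_block(frame["year"].astype(int).tolist(), registry.years),
        _one_hot_block(frame["location_id"].astype(str).tolist(), registry.locations),
        _one_hot_block(frame["genotype_id"].astype(str).tolist(), registry.genotypes),
    ], axis=1)


# ---------------------------------------------------------------------------
# split by genotype-location combination

@dataclass
class SplitMasks:
    """Disjoint train/validation/test row masks keyed by combination."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self):
        masks = np.stack([self.train, self.val, self.test])
        if (masks.sum(axis=0) != 1).any():
            raise ValueError("masks must partition the rows")

    def labels(self) -> np.ndarray:
        out = np.where(self.train, "train", np.where(self.val, "val", "test"))
        return out.astype(object)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"row": np.arange(self.train.size),
                             "split": self.labels()})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int = -1) -> "SplitMasks":
        labels = frame.sort_values("row")["split"].to_numpy()
        return cls(labels == "train", labels == "val", labels == "test", seed)


def split_by_combination(frame: pd.DataFrame,
                         fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                         seed: int = 0) -> SplitMasks:
    """Split rows by unique (genotype, location) combination.

    Combinations are shuffled under ``seed`` and cut 60/20/20 (by the
    given fractions).  Any genotype then absent from train is repaired:
    the combination holding its first occurrence (dataset row order,
    validation searched before test) moves wholesale to train, so no
    combination ever spans two splits and every genotype trains.
    """
    if len(frame) == 0:
        raise ValueError("no records to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    combos = list(dict.fromkeys(
        zip(frame["genotype_id"].astype(str), frame["location_id"].astype(str))))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))
    n_train = int(round(fractions[0] * len(combos)))
    n_temp = len(combos) - n_train
    n_val = n_temp // 2
    assign: dict[tuple[str, str], str] = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            split = "train"
        elif rank < n_train + n_val:
            split = "val"
        else:
            split = "test"
        assign[combos[idx]] = split

    genotypes = frame["genotype_id"].astype(str).to_numpy()
    locations = frame["location_id"].astype(str).to_numpy()
    row_combo = list(zip(genotypes, locations))

    train_genotypes = {g for (g, l), s in assign.items() if s == "train"}
    for g in sorted(set(genotypes) - train_genotypes):
        moved = False
        for target in ("val", "test"):
            for combo in row_combo:  # dataset row order
                if combo[0] == g and assign[combo] == target:
                    assign[combo] = "train"
                    moved = True
                    break
            if moved:
                break
        if not moved:  # pragma: no cover - combos cover every row's genotype
            raise ValueError(f"genotype {g} has no occurrence to repair")

    labels = np.array([assign[c] for c in row_combo])
    return SplitMasks(labels == "train", labels == "val", labels == "test", seed)


# ---------------------------------------------------------------------------
# soil

def read_soil_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"state": str})
    missing = [c for c in ("state",) + SOIL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"soil table missing columns: {missing[:4]}")
    return table


def merge_soil(frame: pd.DataFrame, soil_table: pd.DataFrame) -> np.ndarray:
    """State-keyed soil block (n, 66); every record in a state shares it."""
    table = soil_table.set_index("state")
    states = frame["state"].astype(str)
    missing = sorted(set(states) - set(table.index.astype(str)))
    if missing:
        raise ValueError(f"states absent from soil table: {missing}")
    return table.loc[states, list(SOIL_COLUMNS)].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# feature matrix

@dataclass
class FeatureMatrix:
    """Model-ready design: one-hot blocks + standardized weather (+ soil).

    ``other`` holds the concatenated year/location/genotype one-hot
    blocks; ``weather`` is the standardized (n, 7, 53) tensor; ``soil``
    the optional standardized (n, 66) block.  Column groups for
    importance analysis are derived from the registry block layout and
    the fixed weather variable order.
    """

    other: np.ndarray
    weather: np.ndarray
    y: np.ndarray | None
    registry: CategoryRegistry
    weather_stats: NormalizationStats
    soil: np.ndarray | None = None
    soil_stats: NormalizationStats | None = None
    row_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        n = self.other.shape[0]
        if self.weather.shape != (n, len(WEATHER_VARS), N_PERIODS):
            raise ValueError(f"weather tensor must be (n, 7, {N_PERIODS})")
        if self.y is not None and len(self.y) != n:
            raise ValueError("target length mismatch")
        if self.soil is not None and self.soil.shape != (n, len(SOIL_COLUMNS)):
            raise ValueError("soil block must have 66 columns")
        if self.row_index is None:
            self.row_index = np.arange(n)

    @property
    def n_rows(self) -> int:
        return self.other.shape[0]

    @property
    def n_columns(self) -> int:
        n = self.other.shape[1] + len(WEATHER_VARS) * N_PERIODS
        if self.soil is not None:
            n += self.soil.shape[1]
        return n

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            other=self.other[mask], weather=self.weather[mask],
            y=None if self.y is None else self.y[mask],
            registry=self.registry, weather_stats=self.weather_stats,
            soil=None if self.soil is None else self.soil[mask],
            soil_stats=self.soil_stats, row_index=self.row_index[mask])

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            other=self.other.copy(), weather=self.weather.copy(),
            y=None if self.y is None else self.y.copy(),
            registry=self.registry, weather_stats=self.weather_stats,
            soil=None if self.soil is None else self.soil.copy(),
            soil_stats=self.soil_stats, row_index=self.row_index.copy())


def save_features(features: FeatureMatrix, path: str | Path) -> None:
    """Serialize a FeatureMatrix to one .npz (arrays + JSON sidecars)."""
    arrays = {"other": features.other, "weather": features.weather,
              "row_index": features.row_index,
              "registry": np.array(features.registry.to_json()),
              "weather_stats": np.array(features.weather_stats.to_json())}
    if features.y is not None:
        arrays["y"] = features.y
    if features.soil is not None:
        arrays["soil"] = features.soil
        arrays["soil_stats"] = np.array(features.soil_stats.to_json())
    np.savez_compressed(path, **arrays)


def load_features(path: str | Path) -> FeatureMatrix:
    with np.load(path, allow_pickle=False) as z:
        return FeatureMatrix(
            other=z["other"], weather=z["weather"],
            y=z["y"] if "y" in z else None,
            registry=CategoryRegistry.from_json(str(z["registry"])),
            weather_stats=NormalizationStats.from_json(str(z["weather_stats"])),
            soil=z["soil"] if "soil" in z else None,
            soil_stats=(NormalizationStats.from_json(str(z["soil_stats"]))
                        if "soil_stats" in z else None),
            row_index=z["row_index"])


def weather_column_names() -> tuple[str, ...]:
    return tuple(f"{v}_p{p}" for v in WEATHER_VARS for p in range(1, N_PERIODS + 1))


def build_features(frame: pd.DataFrame, registry: CategoryRegistry,
                   weather_stats: NormalizationStats | None = None,
                   reference_mask: np.ndarray | None = None,
                   soil_table: pd.DataFrame | None = None,
                   soil_stats: NormalizationStats | None = None) -> FeatureMatrix:
    """Encode trial records into a :class:`FeatureMatrix`.

    When ``weather_stats`` is None, statistics are fitted here on
    ``reference_mask`` rows (all rows if None) — pass the train mask to
    keep validation/test information out of the standardization.
    """
    agg = aggregate_weather(weather_tensor(frame))  # (n, 7, 53)
    flat = agg.reshape(len(frame), -1)
    if weather_stats is None:
        weather_stats = fit_normalization(flat, reference_mask,
                                          columns=weather_column_names())
    weather = apply_normalization(flat, weather_stats).reshape(agg.shape)

    soil = soil_block_stats = None
    if soil_table is not None:
        raw_soil = merge_soil(frame, soil_table)
        if soil_stats is None:
            soil_stats = fit_normalization(raw_soil, reference_mask,
                                           columns=SOIL_COLUMNS)
        soil = apply_normalization(raw_soil, soil_stats)
        soil_block_stats = soil_stats

    y = frame["yield"].to_numpy(dtype=float)
    y = None if np.isnan(y).all() else y
    return FeatureMatrix(other=one_hot_encode(frame, registry),
                         weather=weather.astype(np.float64), y=y,
                         registry=registry, weather_stats=weather_stats,
                         soil=soil, soil_stats=soil_block_stats)
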