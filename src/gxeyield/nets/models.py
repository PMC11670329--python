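"""The two yield-regression architectures: CNN and CNN-LSTM.

Both models consume three input streams:

* weather — the standardized (7 x 53) block of 4-day period means; each
  of the seven variables passes through its own 1-D convolution stack
  (same layout, separate weights) with valid padding and ReLU,
* "other" — the concatenated year/location/genotype one-hot vector,
  passed through one wide dense layer with Leaky ReLU,
* soil (optional) — a standardized 66-column block through a dense
  layer of 512 units with Leaky ReLU and ~50% dropout.

The CNN variant flattens and concatenates the conv features and sends
them through a dense layer; the CNN-LSTM variant instead stacks the
conv feature maps as a sequence over the retained temporal axis
(transpose to time-major) and feeds a 128-unit LSTM whose last hidden
state summarizes the season.  The streams are then concatenated and
passed through the combined dense stack to one scalar yield.  Dropout
ratios follow the published positions: (0.5, 0.7, 0.2) for the CNN —
after the post-conv dense layer, after the "other" dense layer, before
the output layer — and (0.5, 0.5, 0.7, 0.2) for the CNN-LSTM, with the
extra rate on the conv output feeding the LSTM.

The conv-stack numerals are declared package defaults (filters 8/12/16,
kernels 9/3/3, strides 1/2/2); they are fully overridable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ..preprocess import N_PERIODS, WEATHER_VARS
from .layers import LSTM, Adam, Conv1D, Dense, Dropout, Layer, LeakyReLU, ReLU

_CNN_DEFAULTS = dict(dense_other_units=2048, dense_combined_units=3200,
                     dropout_rates=(0.5, 0.7, 0.2))
_CNN_LSTM_DEFAULTS = dict(dense_other_units=1596, dense_combined_units=1280,
                          dropout_rates=(0.5, 0.5, 0.7, 0.2))


@dataclass(frozen=True)
class SoilBranchSpec:
    units: int = 512
    dropout: float = 0.5


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters of one regressor; ``None`` fields take the
    variant's published defaults."""

    variant: str = "cnn"
    conv_stack: tuple[tuple[int, int, int], ...] = ((8, 9, 1), (12, 3, 2),
                                                    (16, 3, 2))
    lstm_units: int = 128
    dense_weather_units: int = 1024  # cnn variant: dense after the conv concat
    dense_other_units: int | None = None
    dense_combined_units: int | None = None
    dropout_rates: tuple[float, ...] | None = None
    soil_branch: SoilBranchSpec | None = None
    leaky_slope: float = 0.3

    def __post_init__(self):
        if self.variant not in ("cnn", "cnn_lstm"):
            raise ValueError(f"unknown variant {self.variant!r}")
        defaults = (_CNN_DEFAULTS if self.variant == "cnn"
                    else _CNN_LSTM_DEFAULTS)
        for name in ("dense_other_units", "dense_combined_units",
                     "dropout_rates"):
            if getattr(self, name) is None:
                object.__setattr__(self, name, defaults[name])
        n_drop = 3 if self.variant == "cnn" else 4
        if len(self.dropout_rates) != n_drop:
            raise ValueError(f"{self.variant} takes {n_drop} dropout rates")
        for f, k, s in self.conv_stack:
            if min(f, k, s) < 1:
                raise ValueError("conv stack entries must be positive")

    @classmethod
    def compact(cls, variant: str = "cnn",
                soil: bool = False) -> "ArchitectureSpec":
        """A small desk-scale configuration for fast CPU training."""
        return cls(variant=variant,
                   conv_stack=((4, 9, 1), (6, 3, 2), (8, 3, 2)),
                   lstm_units=16, dense_weather_units=32,
                   dense_other_units=48, dense_combined_units=64,
                   dropout_rates=((0.1, 0.1, 0.05) if variant == "cnn"
                                  else (0.1, 0.1, 0.1, 0.05)),
                   soil_branch=SoilBranchSpec(16, 0.2) if soil else None)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        d = json.loads(text)
        d["conv_stack"] = tuple(tuple(c) for c in d["conv_stack"])
        if d.get("dropout_rates") is not None:
            d["dropout_rates"] = tuple(d["dropout_rates"])
        if d.get("soil_branch") is not None:
            d["soil_branch"] = SoilBranchSpec(**d["soil_branch"])
        return cls(**d)


class _ConvBranch:
    """Conv stack (with ReLU) for one weather variable."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator,
                 name: str):
        self.name = name
        self.layers: list[Layer] = []
        in_channels, length = 1, N_PERIODS
        for filters, kernel, stride in spec.conv_stack:
            conv = Conv1D(in_channels, filters, kernel, stride, rng)
            try:
                length = conv.out_length(length)
            except ValueError as e:
                raise ValueError(f"branch {name}: {e}") from None
            self.layers += [conv, ReLU()]
            in_channels = filters
        self.out_channels, self.out_length = in_channels, length

    def forward(self, x, *, train, rng):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class YieldRegressor:
    """Shared scaffolding of the two variants (streams + combined head)."""

    def __init__(self, spec: ArchitectureSpec, n_other: int,
                 n_soil: int | None = None, seed: int = 0):
        if (n_soil is not None) != (spec.soil_branch is not None):
            raise ValueError("soil input and soil branch must both be "
                             "present or both absent")
        self.spec = spec
        self.n_other, self.n_soil = n_other, n_soil
        rng = np.random.default_rng(seed)
        self.branches = [_ConvBranch(spec, rng, var) for var in WEATHER_VARS]
        self._build_streams(spec, rng)
        self.dense_other = Dense(n_other, spec.dense_other_units, rng)
        self.act_other = LeakyReLU(spec.leaky_slope)
        self.drop_other = Dropout(self._other_dropout_rate())
        if spec.soil_branch is not None:
            self.dense_soil = Dense(n_soil, spec.soil_branch.units, rng)
            self.act_soil = LeakyReLU(spec.leaky_slope)
            self.drop_soil = Dropout(spec.soil_branch.dropout)
        combined_in = self._weather_width() + spec.dense_other_units
        if spec.soil_branch is not None:
            combined_in += spec.soil_branch.units
        self.dense_combined = Dense(combined_in, spec.dense_combined_units, rng)
        self.act_combined = ReLU()
        self.drop_final = Dropout(spec.dropout_rates[-1])
        self.dense_out = Dense(spec.dense_combined_units, 1, rng)

    # variant hooks -------------------------------------------------
    def _build_streams(self, spec, rng):  # pragma: no cover
        raise NotImplementedError

    def _other_dropout_rate(self) -> float:  # pragma: no cover
        raise NotImplementedError

    def _weather_width(self) -> int:  # pragma: no cover
        raise NotImplementedError

    def _weather_forward(self, feats, train, rng):  # pragma: no cover
        raise NotImplementedError

    def _weather_backward(self, dout):  # pragma: no cover
        raise NotImplementedError

    # ---------------------------------------------------------------
    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for b in self.branches:
            out += b.layers
        out += self._stream_layers()
        out += [self.dense_other, self.act_other, self.drop_other]
        if self.spec.soil_branch is not None:
            out += [self.dense_soil, self.act_soil, self.drop_soil]
        out += [self.dense_combined, self.act_combined, self.drop_final,
                self.dense_out]
        return out

    def _check_inputs(self, weather, other, soil):
        n = weather.shape[0]
        if weather.shape[1:] != (len(WEATHER_VARS), N_PERIODS):
            raise ValueError(f"weather branch: expected (n, 7, {N_PERIODS}), "
                             f"got {weather.shape}")
        if other.shape != (n, self.n_other):
            raise ValueError(f"other branch: expected (n, {self.n_other}), "
                             f"got {other.shape}")
        if self.spec.soil_branch is not None:
            if soil is None or soil.shape != (n, self.n_soil):
                raise ValueError(f"soil branch: expected (n, {self.n_soil})")
        elif soil is not None:
            raise ValueError("soil branch: model was built without soil")

    def forward(self, weather, other, soil=None, *, train=False, rng=None):
        self._check_inputs(weather, other, soil)
        feats = [b.forward(weather[:, i:i + 1, :], train=train, rng=rng)
                 for i, b in enumerate(self.branches)]
        w = self._weather_forward(feats, train, rng)
        o = self.drop_other.forward(
            self.act_other.forward(self.dense_other.forward(other)),
            train=train, rng=rng)
        parts = [w, o]
        if self.spec.soil_branch is not None:
            s = self.drop_soil.forward(
                self.act_soil.forward(self.dense_soil.forward(soil)),
                train=train, rng=rng)
            parts.append(s)
        self._widths = [p.shape[1] for p in parts]
        comb = np.concatenate(parts, axis=1)
        z = self.act_combined.forward(self.dense_combined.forward(comb))
        z = self.drop_final.forward(z, train=train, rng=rng)
        return self.dense_out.forward(z)[:, 0]

    def backward(self, dpred):
        dz = self.dense_out.backward(dpred[:, None])
        dz = self.drop_final.backward(dz)
        dcomb = self.dense_combined.backward(self.act_combined.backward(dz))
        cuts = np.cumsum(self._widths)[:-1]
        dparts = np.split(dcomb, cuts, axis=1)
        if self.spec.soil_branch is not None:
            ds = self.drop_soil.backward(dparts[2])
            self.dense_soil.backward(self.act_soil.backward(ds))
        do = self.drop_other.backward(dparts[1])
        self.dense_other.backward(self.act_other.backward(do))
        dfeats = self._weather_backward(dparts[0])
        for b, df in zip(self.branches, dfeats):
            b.backward(df)

    # persistence ---------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, layer in enumerate(self.layers()):
            for name, value in layer.params.items():
                arrays[f"{i}:{name}"] = value
        np.savez(directory / "params.npz", **arrays)
        meta = {"spec": json.loads(self.spec.to_json()),
                "n_other": self.n_other, "n_soil": self.n_soil}
        (directory / "model.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "YieldRegressor":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        spec = ArchitectureSpec.from_json(json.dumps(meta["spec"]))
        model = build_model(spec, meta["n_other"], meta["n_soil"])
        arrays = np.load(directory / "params.npz")
        for i, layer in enumerate(model.layers()):
            for name in layer.params:
                layer.params[name] = arrays[f"{i}:{name}"]
        return model


class CNNRegressor(YieldRegressor):
    """Conv branches -> flatten/concat -> dense -> combined head."""

    def _build_streams(self, spec, rng):
        flat = sum(b.out_channels * b.out_length for b in self.branches)
        self.dense_weather = Dense(flat, spec.dense_weather_units, rng)
        self.act_weather = ReLU()
        self.drop_weather = Dropout(spec.dropout_rates[0])

    def _stream_layers(self):
        return [self.dense_weather, self.act_weather, self.drop_weather]

    def _other_dropout_rate(self):
        return self.spec.dropout_rates[1]

    def _weather_width(self):
        return self.spec.dense_weather_units

    def _weather_forward(self, feats, train, rng):
        self._feat_shapes = [f.shape for f in feats]
        flat = np.concatenate([f.reshape(f.shape[0], -1) for f in feats],
                              axis=1)
        z = self.act_weather.forward(self.dense_weather.forward(flat))
        return self.drop_weather.forward(z, train=train, rng=rng)

    def _weather_backward(self, dout):
        dz = self.drop_weather.backward(dout)
        dflat = self.dense_weather.backward(self.act_weather.backward(dz))
        cuts = np.cumsum([s[1] * s[2] for s in self._feat_shapes])[:-1]
        return [d.reshape(s) for d, s in zip(np.split(dflat, cuts, axis=1),
                                             self._feat_shapes)]


class CNNLSTMRegressor(YieldRegressor):
    """Conv branches -> channel concat -> (time-major) LSTM -> head."""

    def _build_streams(self, spec, rng):
        channels = sum(b.out_channels for b in self.branches)
        self._seq_len = self.branches[0].out_length
        self.drop_conv = Dropout(spec.dropout_rates[0])
        self.lstm = LSTM(channels, spec.lstm_units, rng)
        self.drop_lstm = Dropout(spec.dropout_rates[1])

    def _stream_layers(self):
        return [self.drop_conv, self.lstm, self.drop_lstm]

    def _other_dropout_rate(self):
        return self.spec.dropout_rates[2]

    def _weather_width(self):
        return self.spec.lstm_units

    def _weather_forward(self, feats, train, rng):
        self._channel_cuts = np.cumsum([f.shape[1] for f in feats])[:-1]
        stacked = np.concatenate(feats, axis=1)  # (n, channels, T)
        stacked = self.drop_conv.forward(stacked, train=train, rng=rng)
        seq = np.ascontiguousarray(stacked.transpose(0, 2, 1))  # time-major
        h = self.lstm.forward(seq)
        return self.drop_lstm.forward(h, train=train, rng=rng)

    def _weather_backward(self, dout):
        dh = self.drop_lstm.backward(dout)
        dseq = self.lstm.backward(dh)
        dstacked = self.drop_conv.backward(dseq.transpose(0, 2, 1))
        return np.split(dstacked, self._channel_cuts, axis=1)


def build_model(spec: ArchitectureSpec, n_other: int,
                n_soil: int | None = None, seed: int = 0) -> YieldRegressor:
    """Instantiate an untrained regressor for the given input widths."""
    cls = CNNRegressor if spec.variant == "cnn" else CNNLSTMRegressor
    return cls(spec, n_other, n_soil, seed)
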