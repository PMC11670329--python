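"""End-to-end orchestration: simulate -> preprocess -> train (CNN and
CNN-LSTM) -> GEM ensemble -> evaluate -> importance -> selection.

One :class:`RunConfig` drives a fully seeded run; every artifact lands
under ``out_dir`` and a manifest records inputs, outputs, seeds and
wall-times.  A finished run is idempotent: if the manifest exists the
run is returned as-is unless ``force`` is set.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gem, importance as imp, metrics, selection as sel
from .nets import ArchitectureSpec, TrainedModel, TrainingConfig, fit
from .preprocess import (CategoryRegistry, SplitMasks, build_features,
                         read_trials_csv, split_by_combination,
                         write_trials_csv)
from .synthetic import (SimulationConfig, make_soil_table, simulate_dataset,
                        write_truth_json)

VARIANTS = ("cnn", "cnn_lstm")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    out_dir: str = "run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    split_seed: int = 1
    norm_scope: str = "train"  # fit z-score stats on train rows or "all"
    use_soil: bool = False
    train_iterations: int = 2000
    train_seeds: dict = field(default_factory=lambda: {"cnn": 11,
                                                       "cnn_lstm": 12})
    architectures: dict = field(default_factory=dict)  # variant -> spec
    run_importance: bool = True
    importance_reps: int = 3
    importance_seed: int = 7
    run_selection: bool = True
    selection_k: int = 10
    selection_group_by: str = "state-year"

    def architecture(self, variant: str) -> ArchitectureSpec:
        spec = self.architectures.get(variant)
        if spec is None:
            return ArchitectureSpec.compact(variant, soil=self.use_soil)
        return spec

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", {})
        archs = raw.pop("architectures", {})
        cfg = cls(**raw)
        if sim:
            from .synthetic import EffectSDs, WindowEffect
            if "effect_sds" in sim:
                sim["effect_sds"] = EffectSDs(**sim["effect_sds"])
            if "weather_windows" in sim:
                sim["weather_windows"] = tuple(
                    WindowEffect(w["variable"], tuple(w["periods"]),
                                 w["beta"]) for w in sim["weather_windows"])
            cfg.simulation = SimulationConfig(**sim)
        for variant, spec in archs.items():
            cfg.architectures[variant] = ArchitectureSpec.from_json(
                json.dumps(spec))
        return cfg


@dataclass
class PipelineResult:
    """In-memory view of a finished run plus the artifact manifest."""

    manifest: dict
    frame: pd.DataFrame | None = None
    truth: object | None = None
    features: object | None = None
    masks: SplitMasks | None = None
    models: dict = field(default_factory=dict)
    weights: gem.EnsembleWeights | None = None
    reports: dict = field(default_factory=dict)
    importance: pd.DataFrame | None = None
    selection: pd.DataFrame | None = None


def run_pipeline(config: RunConfig, force: bool = False) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        return PipelineResult(json.loads(manifest_path.read_text()))

    manifest = {"seeds": {"data": config.simulation.seed,
                          "split": config.split_seed,
                          **{f"train_{v}": s
                             for v, s in config.train_seeds.items()},
                          "importance": config.importance_seed},
                "stages": {}, "outputs": {}}

    def stage(name):
        start = time.time()

        def finish(**outputs):
            manifest["stages"][name] = {"seconds": round(time.time() - start, 3)}
            manifest["outputs"].update(outputs)
        return finish

    # simulate ------------------------------------------------------
    done = stage("simulate")
    frame, truth = simulate_dataset(config.simulation)
    data_path, truth_path = out / "data.csv", out / "truth.json"
    write_trials_csv(frame, data_path)
    write_truth_json(truth, truth_path)
    done(data=str(data_path), truth=str(truth_path))

    # preprocess ----------------------------------------------------
    done = stage("preprocess")
    masks = split_by_combination(frame, seed=config.split_seed)
    registry = CategoryRegistry.from_frame(frame)
    reference = masks.train if config.norm_scope == "train" else None
    soil_table = (make_soil_table(frame["state"].tolist(),
                                  seed=config.simulation.seed)
                  if config.use_soil else None)
    features = build_features(frame, registry, reference_mask=reference,
                              soil_table=soil_table)
    split_path = out / "split.csv"
    masks.to_frame().to_csv(split_path, index=False)
    (out / "normalization.json").write_text(features.weather_stats.to_json())
    done(split=str(split_path))

    # train ---------------------------------------------------------
    models: dict[str, TrainedModel] = {}
    for variant in VARIANTS:
        done = stage(f"train_{variant}")
        cfg = TrainingConfig(iterations=config.train_iterations,
                             seed=config.train_seeds.get(variant, 0))
        trained = fit(config.architecture(variant), features, masks.train, cfg)
        model_dir = out / f"model_{variant}"
        trained.save(model_dir)
        models[variant] = trained
        done(**{f"model_{variant}": str(model_dir)})

    # ensemble ------------------------------------------------------
    done = stage("ensemble")
    val_preds = np.column_stack([models[v].predict(features.subset(masks.val))
                                 for v in VARIANTS])
    val_y = features.y[masks.val]
    weights = gem.fit_gem(gem.PredictionSet(val_preds, val_y, VARIANTS))
    weights_path = out / "weights.json"
    weights_path.write_text(json.dumps({
        "model_ids": list(weights.model_ids),
        "weights": weights.weights.tolist(),
        "val_mse": weights.objective}))
    done(weights=str(weights_path))

    # evaluate ------------------------------------------------------
    done = stage("evaluate")
    reports = {}
    for split, mask in (("train", masks.train), ("val", masks.val),
                        ("test", masks.test)):
        sub = features.subset(mask)
        for variant in VARIANTS:
            reports[f"{variant}_{split}"] = metrics.evaluate(
                sub.y, models[variant].predict(sub), split).to_dict()
        P = np.column_stack([models[v].predict(sub) for v in VARIANTS])
        reports[f"gem_{split}"] = metrics.evaluate(
            sub.y, gem.gem_predict(weights, P), split).to_dict()
    report_path = out / "report.json"
    report_path.write_text(json.dumps(reports, indent=1))
    done(report=str(report_path))

    ens_predict = gem.ensemble_predictor([models[v] for v in VARIANTS],
                                         weights)

    # importance ----------------------------------------------------
    importance_frame = None
    if config.run_importance:
        done = stage("importance")
        test_features = features.subset(masks.test)
        groups = imp.define_groups(test_features, "variable")
        result = imp.rmse_change(ens_predict, test_features, groups,
                                 repetitions=config.importance_reps,
                                 seed=config.importance_seed)
        importance_frame = result.to_frame()
        imp_path = out / "importance.csv"
        importance_frame.to_csv(imp_path, index=False)
        done(importance=str(imp_path))

    # selection -----------------------------------------------------
    selection_frame = None
    if config.run_selection:
        done = stage("select")
        selections = sel.select_for_environments(
            ens_predict, frame, registry, features.weather_stats,
            k=min(config.selection_k, len(registry.genotypes)),
            soil_table=soil_table, soil_stats=features.soil_stats)
        selection_frame = sel.selection_gap_report(
            selections, frame, group_by=config.selection_group_by)
        sel_path = out / "selection.csv"
        selection_frame.to_csv(sel_path, index=False)
        done(selection=str(sel_path))

    manifest_path.write_text(json.dumps(manifest, indent=1))
    return PipelineResult(manifest, frame, truth, features, masks, models,
                          weights, reports, importance_frame, selection_frame)
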