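import numpy as np
import pytest

from gxeyield import gem
from gxeyield.nets import ArchitectureSpec, TrainingConfig, fit
from gxeyield.preprocess import (CategoryRegistry, build_features,
                                 split_by_combination)
from gxeyield.synthetic import (EffectSDs, SimulationConfig, WindowEffect,
                                simulate_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    """A small balanced trial dataset with all effect types active."""
    cfg = SimulationConfig(n_locations=10, n_years=4, n_genotypes=40,
                           genotypes_per_env=12, availability_fraction=0.8,
                           seed=5)
    frame, truth = simulate_dataset(cfg)
    return cfg, frame, truth


@pytest.fixture(scope="session")
def small_features(small_dataset):
    cfg, frame, truth = small_dataset
    masks = split_by_combination(frame, seed=1)
    registry = CategoryRegistry.from_frame(frame)
    features = build_features(frame, registry, reference_mask=masks.train)
    return frame, truth, masks, features


@pytest.fixture(scope="session")
def recovery_run():
    """One trained run on genotype-dominant data with an MDNI window.

    Study conditions: ~3,000 records, genotype effect sd 5 bu/ac, a
    single irradiance (MDNI) window over periods 24-26, all other
    effects null, residual sd 1.  Both base models are trained at a
    reduced budget and combined with GEM.  Shared session-wide because
    training is the expensive step.
    """
    cfg = SimulationConfig(
        n_locations=30, n_years=5, n_genotypes=100, genotypes_per_env=25,
        availability_fraction=0.8,
        effect_sds=EffectSDs(genotype=5.0, location=0.0, year=0.0,
                             interaction=0.0, residual=1.0),
        weather_windows=(WindowEffect("MDNI", (24, 26), 5.0),),
        seed=42)
    frame, truth = simulate_dataset(cfg)
    masks = split_by_combination(frame, seed=1)
    registry = CategoryRegistry.from_frame(frame)
    features = build_features(frame, registry, reference_mask=masks.train)
    cnn = fit(ArchitectureSpec.compact("cnn"), features, masks.train,
              TrainingConfig(iterations=2500, seed=11))
    lstm = fit(ArchitectureSpec.compact("cnn_lstm"), features, masks.train,
               TrainingConfig(iterations=1200, seed=12))
    val = features.subset(masks.val)
    P = np.column_stack([cnn.predict(val), lstm.predict(val)])
    weights = gem.fit_gem(gem.PredictionSet(P, val.y, ("cnn", "cnn_lstm")))
    ensemble = gem.ensemble_predictor([cnn, lstm], weights)
    return {"config": cfg, "frame": frame, "truth": truth, "masks": masks,
            "features": features, "registry": registry, "cnn": cnn,
            "lstm": lstm, "weights": weights, "ensemble": ensemble}
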