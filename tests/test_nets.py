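import numpy as np
import pytest
from scipy import stats as sps

from gxeyield.metrics import rmse
from gxeyield.nets import (ArchitectureSpec, TrainedModel, TrainingConfig,
                           build_model, fit, learning_rate_at, train)
from gxeyield.selection import enumerate_environments, predict_all_genotypes

_TINY_KW = dict(conv_stack=((2, 9, 2), (3, 3, 2)), lstm_units=4,
                dense_weather_units=4, dense_other_units=5,
                dense_combined_units=6)


def _tiny_spec(variant, soil=False):
    from gxeyield.nets import SoilBranchSpec
    rates = (0.0, 0.0, 0.0) if variant == "cnn" else (0.0, 0.0, 0.0, 0.0)
    return ArchitectureSpec(variant=variant, dropout_rates=rates,
                            soil_branch=SoilBranchSpec(3, 0.0) if soil else None,
                            **_TINY_KW)


def _tiny_inputs(n=3, n_other=6, n_soil=None, seed=0):
    rng = np.random.default_rng(seed)
    weather = rng.normal(size=(n, 7, 53))
    other = rng.normal(size=(n, n_other))
    soil = None if n_soil is None else rng.normal(size=(n, n_soil))
    y = rng.normal(50, 5, size=n)
    return weather, other, soil, y


def _loss_and_grads(model, weather, other, soil, y):
    pred = model.forward(weather, other, soil)
    err = pred - y
    loss = float(np.mean(err * err))
    for layer in model.layers():
        layer.zero_grads()
    model.backward(2.0 * err / err.size)
    return loss


def _activation_pattern(model):
    """Signature of every rectifier's active set (for kink detection)."""
    masks = []
    for layer in model.layers():
        mask = getattr(layer, "_mask", None)
        if mask is not None:
            masks.append(mask.copy())
    return masks


@pytest.mark.parametrize("variant,soil", [("cnn", False), ("cnn_lstm", False),
                                          ("cnn", True)])
def test_backward_matches_finite_differences(variant, soil):
    """Analytic gradients of every parameter agree with central FD."""
    n_soil = 4 if soil else None
    model = build_model(_tiny_spec(variant, soil), n_other=6, n_soil=n_soil,
                        seed=1)
    jitter = np.random.default_rng(9)
    for layer in model.layers():
        for name in layer.params:  # keep pre-activations off exact zero
            layer.params[name] = layer.params[name] + jitter.normal(
                0.0, 0.01, layer.params[name].shape)
    weather, other, soil_x, y = _tiny_inputs(n_soil=n_soil)
    _loss_and_grads(model, weather, other, soil_x, y)
    rng = np.random.default_rng(0)
    eps = 1e-6
    for layer in model.layers():
        for name, param in layer.params.items():
            grad = layer.grads[name]
            flat = param.reshape(-1)
            idx = np.arange(flat.size)
            if flat.size > 40:
                idx = rng.choice(flat.size, 25, replace=False)
            checked = 0
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                lp = _loss_and_grads(model, weather, other, soil_x, y)
                sig_p = _activation_pattern(model)
                flat[i] = orig - eps
                lm = _loss_and_grads(model, weather, other, soil_x, y)
                sig_m = _activation_pattern(model)
                flat[i] = orig
                if any(not np.array_equal(a, b)
                       for a, b in zip(sig_p, sig_m)):
                    continue  # FD quotient invalid across a rectifier kink
                numeric = (lp - lm) / (2 * eps)
                analytic = grad.reshape(-1)[i]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7)
                checked += 1
            assert checked > 0
            # restore clean grads for the next parameter
            _loss_and_grads(model, weather, other, soil_x, y)


class TestArchitectureSpec:
    def test_published_defaults(self):
        cnn = ArchitectureSpec(variant="cnn")
        assert cnn.dense_other_units == 2048
        assert cnn.dense_combined_units == 3200
        assert cnn.dropout_rates == (0.5, 0.7, 0.2)
        lstm = ArchitectureSpec(variant="cnn_lstm")
        assert lstm.lstm_units == 128
        assert lstm.dense_other_units == 1596
        assert lstm.dense_combined_units == 1280
        assert lstm.dropout_rates == (0.5, 0.5, 0.7, 0.2)

    def test_soil_branch_defaults(self):
        from gxeyield.nets import SoilBranchSpec
        soil = SoilBranchSpec()
        assert soil.units == 512 and soil.dropout == 0.5

    def test_dropout_count_validated(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(variant="cnn", dropout_rates=(0.5, 0.5, 0.7, 0.2))

    def test_json_roundtrip(self):
        spec = _tiny_spec("cnn_lstm")
        assert ArchitectureSpec.from_json(spec.to_json()) == spec


class TestBuildModel:
    def test_scalar_regression_head(self):
        model = build_model(_tiny_spec("cnn"), n_other=6, seed=0)
        weather, other, _, _ = _tiny_inputs(n=5)
        assert model.forward(weather, other).shape == (5,)

    def test_lstm_units_present(self):
        spec = ArchitectureSpec(variant="cnn_lstm")
        model = build_model(spec, n_other=10, seed=0)
        assert model.lstm.units == 128

    def test_shape_mismatch_names_branch(self):
        model = build_model(_tiny_spec("cnn"), n_other=6, seed=0)
        weather, other, _, _ = _tiny_inputs()
        with pytest.raises(ValueError, match="other branch"):
            model.forward(weather, other[:, :4])
        with pytest.raises(ValueError, match="weather branch"):
            model.forward(weather[:, :, :40], other)

    def test_soil_branch_shape_contract(self):
        model = build_model(_tiny_spec("cnn", soil=True), n_other=6,
                            n_soil=4, seed=0)
        weather, other, soil, _ = _tiny_inputs(n_soil=4)
        assert model.forward(weather, other, soil).shape == (3,)
        with pytest.raises(ValueError, match="soil branch"):
            model.forward(weather, other, None)

    def test_variants_consume_identical_inputs(self):
        weather, other, _, _ = _tiny_inputs(n=4)
        preds = {}
        for variant in ("cnn", "cnn_lstm"):
            model = build_model(_tiny_spec(variant), n_other=6, seed=3)
            preds[variant] = model.forward(weather, other)
        assert np.isfinite(preds["cnn"]).all()
        assert np.isfinite(preds["cnn_lstm"]).all()
        assert not np.allclose(preds["cnn"], preds["cnn_lstm"])


class TestTrainingSchedule:
    def test_learning_rate_staircase(self):
        cfg = TrainingConfig()
        assert learning_rate_at(0, cfg) == pytest.approx(4e-4)
        assert learning_rate_at(2499, cfg) == pytest.approx(4e-4)
        assert learning_rate_at(2500, cfg) == pytest.approx(0.000384)
        assert learning_rate_at(5000, cfg) == pytest.approx(4e-4 * 0.96 ** 2)

    def test_batch_size_default_48(self):
        assert TrainingConfig().batch_size == 48

    def test_zero_iterations_leaves_model_at_init(self, small_features):
        _, _, masks, features = small_features
        spec = _tiny_spec("cnn")
        model = build_model(spec, n_other=features.other.shape[1], seed=5)
        reference = build_model(spec, n_other=features.other.shape[1], seed=5)
        trained = train(model, features, masks.train,
                        TrainingConfig(iterations=0, seed=0))
        sub = features.subset(masks.val)
        ref = TrainedModel(reference, spec, TrainingConfig(iterations=0))
        assert trained.predict(sub) == pytest.approx(ref.predict(sub))


class TestTrainedBehavior:
    def test_loss_decreases_over_training(self, recovery_run):
        log = recovery_run["cnn"].loss_log
        assert log[-1][2] < log[0][2]

    def test_beats_constant_mean_baseline(self, recovery_run):
        features, masks = recovery_run["features"], recovery_run["masks"]
        train_sub = features.subset(masks.train)
        pred = recovery_run["cnn"].predict(train_sub)
        baseline = rmse(train_sub.y, np.full_like(train_sub.y,
                                                  train_sub.y.mean()))
        assert rmse(train_sub.y, pred) < baseline

    def test_predicted_genotype_ranking_recovers_truth(self, recovery_run):
        env = enumerate_environments(recovery_run["frame"])[0]
        preds = predict_all_genotypes(
            recovery_run["cnn"].predict, env, recovery_run["registry"],
            recovery_run["features"].weather_stats)
        truth = recovery_run["truth"]
        true_eff = np.array([truth.genotype_effects[g]
                             for g in preds.index])
        rho = sps.spearmanr(preds.to_numpy(), true_eff).statistic
        assert rho > 0.6

    def test_inference_deterministic_and_rowwise(self, recovery_run):
        features, masks = recovery_run["features"], recovery_run["masks"]
        sub = features.subset(masks.val)
        model = recovery_run["cnn"]
        a, b = model.predict(sub), model.predict(sub)
        assert a == pytest.approx(b)
        perm = np.random.default_rng(1).permutation(sub.n_rows)
        assert model.predict(sub.subset(perm)) == pytest.approx(a[perm])

    def test_unseen_genotype_prediction_finite(self, recovery_run):
        features = recovery_run["features"]
        sub = features.subset(np.arange(4))
        sub.other = sub.other.copy()
        blocks = features.registry.blocks
        sub.other[:, blocks["genotype"]] = 0.0  # unseen genotype contract
        assert np.isfinite(recovery_run["cnn"].predict(sub)).all()

    def test_save_load_roundtrip(self, recovery_run, tmp_path):
        model = recovery_run["cnn"]
        sub = recovery_run["features"].subset(np.arange(10))
        model.save(tmp_path / "m")
        back = TrainedModel.load(tmp_path / "m")
        assert back.predict(sub) == pytest.approx(model.predict(sub))

    def test_nonfinite_loss_aborts(self, small_features):
        _, _, masks, features = small_features
        bad = features.copy()
        bad.y = bad.y * 1e200
        model = build_model(_tiny_spec("cnn"),
                            n_other=features.other.shape[1], seed=0)
        with pytest.raises(FloatingPointError):
            train(model, bad, masks.train,
                  TrainingConfig(iterations=50, seed=0))
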