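import numpy as np
import pandas as pd
import pytest

from gxeyield.preprocess import (N_DAYS, N_PERIODS, SOIL_COLUMNS,
                                 WEATHER_VARS, CategoryRegistry,
                                 aggregate_weather, apply_normalization,
                                 build_features, fit_normalization,
                                 load_features, merge_soil, one_hot_encode,
                                 read_trials_csv, save_features,
                                 split_by_combination, write_trials_csv)
from gxeyield.synthetic import make_soil_table


class TestAggregateWeather:
    def test_output_length_is_53(self):
        out = aggregate_weather(np.random.default_rng(0).normal(size=214))
        assert out.shape == (N_PERIODS,)

    def test_constant_series(self):
        assert aggregate_weather(np.full(214, 3.25)) == pytest.approx(
            np.full(53, 3.25))

    def test_arithmetic_oracle_on_ramp(self):
        out = aggregate_weather(np.arange(1.0, 215.0))
        assert out[0] == pytest.approx(2.5)      # mean of days 1..4
        assert out[52] == pytest.approx(211.5)   # mean of days 209..214

    def test_mean_conservation_with_period_weights(self):
        series = np.random.default_rng(1).normal(size=214)
        weights = np.array([4.0] * 52 + [6.0]) / 214.0
        assert series.mean() == pytest.approx(
            float(aggregate_weather(series) @ weights))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            aggregate_weather(np.zeros(213))

    def test_batched_aggregation_matches_rowwise(self):
        block = np.random.default_rng(2).normal(size=(3, 7, 214))
        out = aggregate_weather(block)
        assert out.shape == (3, 7, 53)
        assert out[1, 2] == pytest.approx(aggregate_weather(block[1, 2]))


class TestNormalization:
    def test_hand_case_population_sd(self):
        stats = fit_normalization(np.array([[1.0], [2.0], [3.0]]))
        assert stats.mean[0] == pytest.approx(2.0)
        assert stats.sd[0] == pytest.approx(0.8165, abs=1e-4)
        out = apply_normalization(np.array([[3.0]]), stats)
        assert out[0, 0] == pytest.approx(1.2247, abs=1e-4)

    def test_center_maps_to_zero(self):
        stats = fit_normalization(np.array([[1.0], [2.0], [3.0]]))
        assert apply_normalization(np.array([[2.0]]), stats)[0, 0] == 0.0

    def test_constant_column_flagged_and_zeroed(self):
        stats = fit_normalization(np.full((4, 1), 7.0))
        assert stats.zero_variance[0]
        assert apply_normalization(np.array([[9.0]]), stats)[0, 0] == 0.0

    def test_reference_rows_standardize_to_unit_scale(self):
        rng = np.random.default_rng(0)
        X = rng.normal(10, 3, size=(50, 4))
        mask = np.zeros(50, dtype=bool)
        mask[:30] = True
        stats = fit_normalization(X, mask)
        Z = apply_normalization(X, stats)[mask]
        assert Z.mean(axis=0) == pytest.approx(np.zeros(4), abs=1e-9)
        assert Z.std(axis=0, ddof=0) == pytest.approx(np.ones(4), abs=1e-9)

    def test_reference_scope_changes_stats(self):
        X = np.arange(20, dtype=float).reshape(10, 2)
        mask = np.array([True] * 5 + [False] * 5)
        assert fit_normalization(X, mask).mean[0] != \
            fit_normalization(X).mean[0]

    def test_small_reference_and_mismatch_errors(self):
        with pytest.raises(ValueError):
            fit_normalization(np.ones((1, 2)))
        stats = fit_normalization(np.ones((3, 2)) * np.arange(3)[:, None])
        with pytest.raises(ValueError):
            apply_normalization(np.ones((1, 3)), stats)


class TestOneHot:
    def test_real_cardinalities_give_6010_columns(self):
        registry = CategoryRegistry(
            years=tuple(range(2003, 2016)),
            locations=tuple(f"L{i}" for i in range(159)),
            genotypes=tuple(f"G{i}" for i in range(5838)))
        assert registry.n_columns == 6010
        frame = pd.DataFrame({"year": [2003], "location_id": ["L5"],
                              "genotype_id": ["G17"]})
        block = one_hot_encode(frame, registry)
        assert block.shape == (1, 6010)
        assert block.sum() == 3.0

    def test_single_category_always_one(self):
        registry = CategoryRegistry((2010,), ("L1",), ("G1",))
        frame = pd.DataFrame({"year": [2010, 2010], "location_id": ["L1"] * 2,
                              "genotype_id": ["G1"] * 2})
        assert one_hot_encode(frame, registry) == pytest.approx(
            np.ones((2, 3)))

    def test_unseen_genotype_encodes_as_zero_block(self):
        registry = CategoryRegistry((2010,), ("L1",), ("G1", "G2"))
        frame = pd.DataFrame({"year": [2010], "location_id": ["L1"],
                              "genotype_id": ["G_NEW"]})
        row = one_hot_encode(frame, registry)[0]
        blocks = registry.blocks
        assert row[blocks["genotype"]].sum() == 0.0
        assert row[blocks["year"]].sum() == 1.0
        assert row[blocks["location"]].sum() == 1.0

    def test_row_sums_one_per_block_for_known_categories(self, small_features):
        frame, _, _, features = small_features
        blocks = features.registry.blocks
        for name in ("year", "location", "genotype"):
            sums = features.other[:, blocks[name]].sum(axis=1)
            assert sums == pytest.approx(np.ones(len(frame)))


class TestSplit:
    def test_no_combination_overlap_and_full_coverage(self, small_dataset):
        _, frame, _ = small_dataset
        masks = split_by_combination(frame, seed=3)
        combos = frame["genotype_id"] + "|" + frame["location_id"]
        sets = [set(combos[m]) for m in (masks.train, masks.val, masks.test)]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) \
            and not (sets[1] & sets[2])
        assert set(frame["genotype_id"]) == set(
            frame["genotype_id"][masks.train])

    def test_deterministic_under_seed(self, small_dataset):
        _, frame, _ = small_dataset
        a = split_by_combination(frame, seed=9)
        b = split_by_combination(frame, seed=9)
        assert np.array_equal(a.train, b.train)
        assert np.array_equal(a.val, b.val)

    def test_100_combinations_split_60_20_20(self):
        # full 10x10 cross, one record per combination, no repair possible
        # to change counts when every genotype lands in train
        rows = []
        for g in range(10):
            for l in range(10):
                rows.append({"genotype_id": f"G{g}", "location_id": f"L{l}"})
        frame = pd.DataFrame(rows)
        masks = split_by_combination(frame, seed=4)
        sizes = (masks.train.sum(), masks.val.sum(), masks.test.sum())
        # repair only ever grows train
        assert sizes[0] >= 60 and sum(sizes) == 100
        if sizes[0] == 60:
            assert sizes[1] == 20 and sizes[2] == 20

    def test_singleton_genotype_forced_into_train(self):
        rows = [{"genotype_id": f"G{i}", "location_id": f"L{j}"}
                for i in range(3) for j in range(8)]
        rows.append({"genotype_id": "G_RARE", "location_id": "L0"})
        frame = pd.DataFrame(rows)
        for seed in range(10):
            masks = split_by_combination(frame, seed=seed)
            assert masks.train[len(frame) - 1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            split_by_combination(pd.DataFrame({"genotype_id": [],
                                               "location_id": []}))


class TestSoil:
    def test_66_columns_and_state_sharing(self):
        table = make_soil_table(["S01", "S02"], seed=1)
        frame = pd.DataFrame({"state": ["S01", "S01", "S02"]})
        block = merge_soil(frame, table)
        assert block.shape == (3, 66)
        assert len(SOIL_COLUMNS) == 66
        assert block[0] == pytest.approx(block[1])
        assert not np.allclose(block[0], block[2])

    def test_missing_state_listed_in_error(self):
        table = make_soil_table(["S01"], seed=1)
        frame = pd.DataFrame({"state": ["S01", "S99"]})
        with pytest.raises(ValueError, match="S99"):
            merge_soil(frame, table)


class TestFeatureMatrix:
    def test_column_identity_at_real_cardinalities(self, small_dataset):
        _, frame, _ = small_dataset
        registry = CategoryRegistry(
            years=tuple(range(2003, 2016)),
            locations=tuple(f"L{i}" for i in range(159)),
            genotypes=tuple(f"G{i}" for i in range(5838)))
        features = build_features(frame.head(3), registry)
        assert features.n_columns == 6010 + 53 * 7 == 6381

    def test_roundtrip_csv(self, small_dataset, tmp_path):
        _, frame, _ = small_dataset
        path = tmp_path / "trials.csv"
        write_trials_csv(frame.head(20), path)
        back = read_trials_csv(path)
        pd.testing.assert_frame_equal(frame.head(20).reset_index(drop=True),
                                      back, check_dtype=False)

    def test_feature_file_roundtrip(self, small_features, tmp_path):
        _, _, _, features = small_features
        path = tmp_path / "features.npz"
        save_features(features, path)
        back = load_features(path)
        assert back.other == pytest.approx(features.other)
        assert back.weather == pytest.approx(features.weather)
        assert back.y == pytest.approx(features.y)
        assert back.registry == features.registry

    def test_weather_standardized_on_reference(self, small_features):
        _, _, masks, features = small_features
        flat = features.weather[masks.train].reshape(masks.train.sum(), -1)
        keep = ~features.weather_stats.zero_variance
        assert flat.mean(axis=0)[keep] == pytest.approx(
            np.zeros(keep.sum()), abs=1e-9)
        assert flat.std(axis=0, ddof=0)[keep] == pytest.approx(
            np.ones(keep.sum()), abs=1e-9)
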