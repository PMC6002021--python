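import numpy as np
import pandas as pd
import pytest

from teneeg import (
    DegenerateDataError,
    EpochSet,
    FeatureDescriptor,
    ModelSpec,
    ParameterError,
    ShapeMismatchError,
    build_feature_matrix,
    build_feature_tensor,
    contributions,
    default_hopls_grid,
    default_pls_grid,
    evaluation_summary,
    extract_features,
    grid_search,
    loocv,
    normalize_responses,
    rmse,
)
from teneeg.feature_tensor import cell_descriptor, _layout_cells


class TestNormalization:
    def test_three_point_column(self):
        yn, params = normalize_responses(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(yn.ravel(), [-1.0, 0.0, 1.0])  # sd divisor N-1
        assert params.std[0] == pytest.approx(1.0)

    def test_idempotent(self, rng):
        y = rng.standard_normal((50, 3))
        yn, _ = normalize_responses(y)
        yn2, _ = normalize_responses(yn)
        np.testing.assert_allclose(yn2, yn, atol=1e-12)

    def test_zero_mean_unit_variance(self, rng):
        yn, _ = normalize_responses(rng.uniform(1, 5, size=(44, 3)))
        np.testing.assert_allclose(yn.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(yn.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_constant_column_rejected(self):
        with pytest.raises(DegenerateDataError):
            normalize_responses(np.full((5, 1), 5.0))

    def test_inverse_round_trip(self, rng):
        y = rng.uniform(1, 9, size=(20, 3))
        yn, params = normalize_responses(y)
        np.testing.assert_allclose(params.inverse(yn), y, atol=1e-10)


class TestRMSE:
    def test_perfect_prediction(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_unit_offset(self):
        assert rmse([1.0, 1.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_hand_computed(self):
        assert rmse([2.0, 0.0, 1.0], [0.0, 0.0, 1.0]) == pytest.approx(
            np.sqrt(4.0 / 3.0)
        )

    def test_length_mismatch(self):
        with pytest.raises(ShapeMismatchError):
            rmse([1.0, 2.0], [1.0])


def tiny_features(rng, n=12, m=3):
    labels = [f"C{i + 1}" for i in range(m)]
    trials = [rng.standard_normal((m, 256)) for _ in range(n)]
    return extract_features(EpochSet("s", trials, labels, 256.0))


class TestLOOCV:
    def test_mean_model_scores_near_one(self, rng):
        feats = tiny_features(rng, n=44)
        y = rng.uniform(1, 5, size=(44, 3))
        result = loocv(build_feature_matrix(feats), y, ModelSpec.pls(0))
        # baseline on the normalized scale: RMSE ~ 1 up to fold renormalization
        for s, v in result.rmse_per_scale.items():
            assert 0.9 < v < 1.15

    def test_fold_count_equals_n(self, rng):
        feats = tiny_features(rng, n=44)
        y = rng.uniform(1, 5, size=(44, 3))
        result = loocv(build_feature_matrix(feats), y, ModelSpec.pls(1))
        assert result.n_folds == 44
        assert result.predictions.shape == (44, 3)

    def test_strong_signal_beats_baseline(self):
        from teneeg import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_channels=8, n_trials=44, rating_noise_sd=0.3, duration_range=(4, 6)
        )
        data = simulate_dataset(cfg, seed=7, truth_kind="low_rank", rank=2)
        feats = extract_features(data.epoch_sets[0])
        y = data.ratings.for_subject("s01")
        result = loocv(build_feature_matrix(feats), y, ModelSpec.pls(5))
        assert np.mean(list(result.rmse_per_scale.values())) < 0.7

    def test_infeasible_hyperparameters_rejected(self, rng):
        feats = tiny_features(rng, n=10)
        y = rng.uniform(1, 5, size=(10, 3))
        with pytest.raises(ParameterError):
            loocv(build_feature_matrix(feats), y, ModelSpec.pls(9))  # > N-2
        with pytest.raises(ParameterError):
            loocv(build_feature_tensor(feats), y, ModelSpec.hopls(4, 2, 2, 1))

    def test_too_few_trials(self, rng):
        feats = tiny_features(rng, n=2)
        with pytest.raises(ParameterError):
            loocv(
                build_feature_matrix(feats),
                np.array([[1.0, 2, 3], [2, 3, 4]]),
                ModelSpec.pls(1),
            )

    def test_no_leakage_permuted_responses_show_no_skill(self, rng):
        feats = tiny_features(rng, n=30)
        x = build_feature_matrix(feats)
        scores = []
        for seed in range(3):
            r = np.random.default_rng(seed)
            y = r.uniform(1, 5, size=(30, 3))
            result = loocv(x, y[r.permutation(30)], ModelSpec.pls(3))
            scores.append(np.mean(list(result.rmse_per_scale.values())))
        assert np.mean(scores) >= 0.95


class TestGridSearch:
    def test_default_grids_match_protocol(self):
        assert default_pls_grid() == list(range(1, 44))
        grid = default_hopls_grid()
        assert len(grid) == 7 * 7 * 5 * 5 == 1225
        l1s, l2s, l3s, r2s = map(set, zip(*grid))
        assert l1s == l2s == set(range(1, 8))
        assert l3s == r2s == set(range(1, 6))

    def test_single_point_grid_equals_loocv(self, rng):
        feats = tiny_features(rng, n=15)
        x = build_feature_matrix(feats)
        y = rng.uniform(1, 5, size=(15, 3))
        best, table = grid_search(x, y, "pls", grid=[3])
        direct = loocv(x, y, ModelSpec.pls(3))
        assert best.rmse_per_scale == direct.rmse_per_scale
        assert len(table) == 1

    def test_pls_path_matches_individual_fits(self, rng):
        feats = tiny_features(rng, n=15)
        x = build_feature_matrix(feats)
        y = rng.uniform(1, 5, size=(15, 3))
        _, table = grid_search(x, y, "pls", grid=[1, 2, 4])
        for r1 in (1, 2, 4):
            direct = loocv(x, y, ModelSpec.pls(r1))
            row = table[table["r1"] == r1].iloc[0]
            for s in ("MOS", "VAL", "ARL"):
                assert row[f"rmse_{s}"] == pytest.approx(
                    direct.rmse_per_scale[s], abs=1e-10
                )

    def test_hopls_path_matches_individual_fits(self, rng):
        feats = tiny_features(rng, n=12)
        t = build_feature_tensor(feats)
        y = rng.uniform(1, 5, size=(12, 3))
        _, table = grid_search(t, y, "hopls", grid=[(2, 2, 2, 1), (2, 2, 2, 2)])
        for r2 in (1, 2):
            direct = loocv(t, y, ModelSpec.hopls(2, 2, 2, r2))
            row = table[table["r2"] == r2].iloc[0]
            for s in ("MOS", "VAL", "ARL"):
                assert row[f"rmse_{s}"] == pytest.approx(
                    direct.rmse_per_scale[s], abs=1e-10
                )

    def test_infeasible_points_skipped_with_warning(self, rng):
        feats = tiny_features(rng, n=10, m=3)
        t = build_feature_tensor(feats)
        y = rng.uniform(1, 5, size=(10, 3))
        with pytest.warns(UserWarning, match="skipped"):
            best, table = grid_search(
                t, y, "hopls", grid=[(2, 2, 2, 1), (4, 2, 2, 1)]
            )
        assert len(table) == 1

    def test_deterministic(self, rng):
        feats = tiny_features(rng, n=12)
        x = build_feature_matrix(feats)
        y = rng.uniform(1, 5, size=(12, 3))
        b1, t1 = grid_search(x, y, "pls", grid=[1, 2, 3])
        b2, t2 = grid_search(x, y, "pls", grid=[1, 2, 3])
        assert b1.hyperparams == b2.hyperparams
        pd.testing.assert_frame_equal(t1, t2)


def test_summary_has_table_schema(rng):
    feats = tiny_features(rng, n=12)
    y = rng.uniform(1, 5, size=(12, 3))
    pls_res = loocv(build_feature_matrix(feats), y, ModelSpec.pls(2))
    hop_res = loocv(build_feature_tensor(feats), y, ModelSpec.hopls(2, 2, 2, 1))
    df = evaluation_summary(pls_res, hop_res)
    assert list(df.columns) == [
        "scale", "rmse_vector", "rmse_tensor", "R1", "L1", "L2", "L3", "R2",
    ]
    assert list(df["scale"]) == ["MOS", "VAL", "ARL"]


class TestContributions:
    labels = ["C1", "C2", "C3", "C4"]
    bands = ["delta", "theta", "alpha", "beta", "gamma"]

    def test_single_nonzero_tensor_entry(self):
        coef = np.zeros((4, 4, 5, 3))
        coef[2, 0, 2, :] = 1.0  # (m1=3, m2=1, alpha) in 1-based indexing
        report = contributions(
            coef, channel_labels=self.labels, band_names=self.bands, k=1
        )
        top = report.top_features["MOS"].iloc[0]
        assert (top["kind"], top["channel1"], top["channel2"], top["band"]) == (
            "PWD", "C3", "C1", "alpha",
        )
        assert report.kind_counts.loc["MOS"].to_dict() == {
            "PSD": 0, "PWD": 1, "PHD": 0,
        }

    def test_equal_magnitudes_tie_break_by_layout_order(self):
        m, f = 4, 5
        i = f * m * m
        index_map = [
            cell_descriptor(a, b, c, self.labels, self.bands)
            for a, b, c in _layout_cells(m, f)
        ]
        report = contributions(np.ones((i, 1)), index_map, k=i)
        # counts are the layout composition: M PSD, M(M-1)/2 each pair kind per band
        assert report.kind_counts.loc["MOS"].to_dict() == {
            "PSD": f * m, "PWD": f * 6, "PHD": f * 6,
        }
        assert report.top_features["MOS"].iloc[0]["kind"] == "PSD"
        assert (report.band_counts.loc["MOS"] == m * m).all()

    def test_k_clipped_with_warning(self):
        index_map = [
            cell_descriptor(a, b, c, self.labels[:2], self.bands[:1])
            for a, b, c in _layout_cells(2, 1)
        ]
        with pytest.warns(UserWarning, match="clip"):
            report = contributions(np.ones((4, 1)), index_map, k=100)
        assert len(report.top_features["MOS"]) == 4

    def test_pair_aggregation_sums_both_kinds_and_bands(self):
        coef = np.zeros((4, 4, 5, 1))
        coef[2, 0, 2, 0] = 1.0   # PWD C3-C1 alpha
        coef[0, 2, 1, 0] = 2.0   # PHD C1-C3 theta -> same unordered pair
        coef[3, 1, 0, 0] = 0.5   # PWD C4-C2 delta
        report = contributions(
            coef, channel_labels=self.labels, band_names=self.bands, k=4,
            scale_names=("MOS",),
        )
        pairs = report.top_pairs["MOS"]
        assert pairs.iloc[0]["magnitude"] == pytest.approx(3.0)
        assert {pairs.iloc[0]["channel1"], pairs.iloc[0]["channel2"]} == {"C1", "C3"}
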