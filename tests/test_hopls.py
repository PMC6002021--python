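import numpy as np
import pytest

from teneeg import (
    ParameterError,
    ShapeMismatchError,
    fit_hopls,
    fit_pls,
    hopls_coefficients,
    load_hopls,
    predict_hopls,
    predict_pls,
    save_hopls,
    tucker_hooi,
)
from teneeg.hopls import mode_dot, multi_mode_dot, unfold, fold


def orthonormal(rng, n, k):
    q, _ = np.linalg.qr(rng.standard_normal((n, k)))
    return q


def tucker_model_data(rng, n=40, m=6, f=3, j=3, n_components=3, ranks=(2, 2, 2),
                      d_strengths=(5.0, 3.0, 1.5), noise=0.0):
    """Data generated exactly from the latent multilinear model.

    Scores are mean-zero and orthonormal, and the channel-1 loading subspaces
    of different components are mutually orthogonal, which makes the greedy
    per-component extraction identifiable (it recovers the construction
    exactly in the noiseless case).
    """
    g0 = rng.standard_normal((n, n_components))
    g0 -= g0.mean(axis=0)
    scores, _ = np.linalg.qr(g0)
    q_all = orthonormal(rng, m, m)
    qy = orthonormal(rng, j, j)
    l1, l2, l3 = ranks
    x = np.zeros((n, m, m, f))
    y = np.zeros((n, j))
    for r in range(n_components):
        p1 = q_all[:, l1 * r : l1 * (r + 1)]
        p2 = orthonormal(rng, m, l2)
        p3 = orthonormal(rng, f, l3)
        core = rng.standard_normal((1, l1, l2, l3))
        slab = multi_mode_dot(core, [p1, p2, p3], (1, 2, 3))[0]
        x += scores[:, r][:, None, None, None] * slab
        y += d_strengths[r] * np.outer(scores[:, r], qy[:, r])
    if noise:
        x = x + noise * rng.standard_normal(x.shape)
        y = y + noise * rng.standard_normal(y.shape)
    return x, y


class TestTensorPrimitives:
    def test_unfold_fold_round_trip(self, rng):
        t = rng.standard_normal((3, 4, 5, 2))
        for mode in range(4):
            assert np.array_equal(fold(unfold(t, mode), mode, t.shape), t)

    def test_mode_dot_matches_unfolding_definition(self, rng):
        t = rng.standard_normal((3, 4, 5))
        a = rng.standard_normal((6, 4))
        out = mode_dot(t, a, 1)
        np.testing.assert_allclose(unfold(out, 1), a @ unfold(t, 1), atol=1e-12)

    def test_hooi_recovers_exact_low_rank_tensor(self, rng):
        factors = [orthonormal(rng, s, 2) for s in (5, 6, 4)]
        core = rng.standard_normal((2, 2, 2))
        t = multi_mode_dot(core, factors, (0, 1, 2))
        fitted, fitted_core = tucker_hooi(t, (2, 2, 2))
        recon = multi_mode_dot(fitted_core, fitted, (0, 1, 2))
        assert np.linalg.norm(recon - t) < 1e-9 * np.linalg.norm(t)
        for fac in fitted:
            np.testing.assert_allclose(fac.T @ fac, np.eye(2), atol=1e-10)

    def test_hooi_rank_bounds(self, rng):
        with pytest.raises(ParameterError):
            tucker_hooi(rng.standard_normal((3, 4, 5)), (4, 2, 2))


class TestFit:
    def test_noiseless_model_recovered_exactly(self, rng):
        x, y = tucker_model_data(rng)
        model = fit_hopls(x, y, 3, 2, 2, 2)
        v_rel = model.y_residual_norms[-1] / model.y_residual_norms[0]
        assert v_rel < 1e-6
        pred = predict_hopls(model, x)
        assert np.linalg.norm(pred - y) / np.linalg.norm(y) < 1e-6

    def test_loadings_orthonormal_and_scores_unit(self, rng):
        x = rng.standard_normal((20, 5, 5, 3))
        y = rng.standard_normal((20, 3))
        model = fit_hopls(x, y, 3, 2, 2, 2)
        for comp in model.components:
            for p in comp.loadings:
                np.testing.assert_allclose(
                    p.T @ p, np.eye(p.shape[1]), atol=1e-8
                )
            assert np.linalg.norm(comp.score) == pytest.approx(1.0, abs=1e-10)

    def test_residual_norms_monotone(self, rng):
        x = rng.standard_normal((20, 5, 5, 3))
        y = rng.standard_normal((20, 3))
        model = fit_hopls(x, y, 4, 2, 2, 2)
        assert np.all(np.diff(model.x_residual_norms) < 1e-10)
        assert np.all(np.diff(model.y_residual_norms) < 1e-10)

    @pytest.mark.parametrize("bad", [dict(l1=8), dict(l2=8), dict(l3=4), dict(r2=0)])
    def test_rank_bounds_checked(self, rng, bad):
        x = rng.standard_normal((15, 7, 7, 3))
        y = rng.standard_normal((15, 3))
        kwargs = dict(n_components=2, l1=2, l2=2, l3=2)
        kwargs.update({{"l1": "l1", "l2": "l2", "l3": "l3", "r2": "n_components"}[k]: v
                       for k, v in bad.items()})
        with pytest.raises(ParameterError):
            fit_hopls(x, y, kwargs["n_components"], kwargs["l1"], kwargs["l2"], kwargs["l3"])

    def test_grid_extremes_accepted(self, rng):
        # the full hyperparameter ranges L1, L2 in 1..7 and L3, R2 in 1..5
        # are valid on a 7-channel, 5-band tensor
        x = rng.standard_normal((16, 7, 7, 5))
        y = rng.standard_normal((16, 3))
        fit_hopls(x, y, 1, 7, 7, 5)
        fit_hopls(x, y, 5, 1, 1, 1)

    def test_early_stop_records_achieved_components(self, rng):
        x, y = tucker_model_data(rng, n_components=2, d_strengths=(3.0, 1.0))
        with pytest.warns(UserWarning, match="exhausted"):
            model = fit_hopls(x, y, 6, 2, 2, 2)
        assert model.n_components < 6

    def test_determinism_bit_identical_model_files(self, rng, tmp_path):
        x = rng.standard_normal((18, 5, 5, 3))
        y = rng.standard_normal((18, 3))
        save_hopls(fit_hopls(x, y, 3, 2, 2, 2), tmp_path / "a.npz")
        save_hopls(fit_hopls(x.copy(), y.copy(), 3, 2, 2, 2), tmp_path / "b.npz")
        assert (tmp_path / "a.npz").read_bytes() == (tmp_path / "b.npz").read_bytes()


class TestReductionToPLS:
    def test_full_loading_ranks_reduce_to_pls(self, rng):
        n, m, f, j = 20, 4, 2, 3
        x = rng.standard_normal((n, m, m, f))
        y = rng.standard_normal((n, j))
        x_new = rng.standard_normal((6, m, m, f))
        for r in (1, 2, 3):
            hop = fit_hopls(x, y, r, m, m, f)
            pls = fit_pls(x.reshape(n, -1), y, r, tol=1e-13, max_iter=10000)
            np.testing.assert_allclose(
                predict_hopls(hop, x_new),
                predict_pls(pls, x_new.reshape(6, -1)),
                atol=1e-6,
            )


class TestPredict:
    def test_training_mean_tensor_predicts_response_mean(self, rng):
        x = rng.standard_normal((20, 5, 5, 3))
        y = rng.standard_normal((20, 3))
        model = fit_hopls(x, y, 2, 2, 2, 2)
        np.testing.assert_allclose(
            predict_hopls(model, x.mean(axis=0)), y.mean(axis=0), atol=1e-10
        )

    def test_shape_mismatch_rejected(self, rng):
        model = fit_hopls(
            rng.standard_normal((15, 5, 5, 3)), rng.standard_normal((15, 2)), 1, 2, 2, 2
        )
        with pytest.raises(ShapeMismatchError):
            predict_hopls(model, np.zeros((2, 4, 4, 3)))

    def test_held_out_error_decreases_with_training_size(self):
        # with observation noise sigma, held-out RMSE approaches sigma as N grows
        sigma = 0.1
        errors = []
        for n in (20, 40, 80):
            errs = []
            for seed in (0, 1, 2):
                rng = np.random.default_rng(seed)
                x, y = tucker_model_data(
                    rng, n=n + 20, n_components=2, d_strengths=(5.0, 3.0),
                    noise=sigma,
                )
                model = fit_hopls(x[:n], y[:n], 2, 2, 2, 2)
                pred = predict_hopls(model, x[n:])
                errs.append(np.sqrt(np.mean((pred - y[n:]) ** 2)))
            errors.append(np.mean(errs))
        assert errors[2] < errors[0]
        assert errors[2] < 3 * sigma


class TestCoefficients:
    def test_coefficients_reproduce_predictions(self, rng):
        x = rng.standard_normal((18, 5, 5, 3))
        y = rng.standard_normal((18, 3))
        model = fit_hopls(x, y, 3, 2, 2, 2)
        w = hopls_coefficients(model)
        x_new = rng.standard_normal((100, 5, 5, 3))
        via_w = (
            np.tensordot(x_new - model.x_mean, w, axes=3) + model.y_mean
        )
        np.testing.assert_allclose(via_w, predict_hopls(model, x_new), atol=1e-8)

    def test_rank_one_model_gives_separable_coefficients(self, rng):
        x = rng.standard_normal((18, 5, 5, 3))
        y = rng.standard_normal(18)
        model = fit_hopls(x, y, 1, 1, 1, 1)
        w = hopls_coefficients(model)[:, :, :, 0]
        # a (1,1,1)-rank single component is an outer product across modes
        u, s, _ = np.linalg.svd(unfold(w, 0))
        assert s[1] < 1e-10 * s[0]
        u, s, _ = np.linalg.svd(unfold(w, 2))
        assert s[1] < 1e-10 * s[0]

    def test_zero_response_gives_zero_coefficients(self, rng):
        x = rng.standard_normal((15, 4, 4, 3))
        with pytest.warns(UserWarning):
            model = fit_hopls(x, np.zeros((15, 2)), 2, 2, 2, 2)
        assert model.n_components == 0
        assert np.all(hopls_coefficients(model) == 0)


def test_serialization_round_trip(rng, tmp_path):
    x = rng.standard_normal((15, 4, 4, 3))
    y = rng.standard_normal((15, 3))
    model = fit_hopls(x, y, 2, 2, 2, 2)
    save_hopls(model, tmp_path / "m.npz")
    back = load_hopls(tmp_path / "m.npz")
    x_new = rng.standard_normal((5, 4, 4, 3))
    np.testing.assert_array_equal(
        predict_hopls(back, x_new), predict_hopls(model, x_new)
    )
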