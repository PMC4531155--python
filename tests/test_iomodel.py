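"""KRLS estimator, hyperparameter selection and evaluation metrics."""

import warnings

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.kernel_ridge import KernelRidge

from evokedio import iomodel as io


def brute_force_krls(x, y, kernel, sigma, lam):
    """Independent dense solve of (K + lam n I) a = y - mean(y)."""
    x = np.asarray(x, dtype=float)[:, None]
    n = x.shape[0]
    if kernel == "linear":
        K = x @ x.T
    else:
        K = np.exp(-((x - x.T) ** 2) / sigma)
    a = np.linalg.solve(K + lam * n * np.eye(n), y - np.mean(y))
    return a, float(np.mean(y))


class TestGramMatrix:
    def test_rbf_unit_diagonal_and_hand_values(self):
        x = np.array([0.0, 1.0, 3.0])
        K = io.gram_matrix(x, "rbf", sigma=2.0)
        assert np.allclose(np.diag(K), 1.0)
        assert K[0, 1] == pytest.approx(np.exp(-1 / 2))
        assert K[0, 2] == pytest.approx(np.exp(-9 / 2))
        assert np.allclose(K, K.T)

    def test_rbf_saturates_to_one_for_huge_sigma(self):
        K = io.gram_matrix([0.0, 5.0, 9.0], "rbf", sigma=1e12)
        assert np.allclose(K, 1.0, atol=1e-9)

    def test_linear_is_outer_product(self):
        x = np.array([1.0, 2.0, -3.0])
        assert np.allclose(io.gram_matrix(x, "linear"), np.outer(x, x))


class TestKRLSRegressor:
    def test_matches_brute_force_solve(self):
        rng = np.random.default_rng(0)
        for kernel in ("rbf", "linear"):
            for _ in range(5):
                n = int(rng.integers(3, 30))
                x = rng.uniform(0, 1, n)
                y = rng.normal(0, 1, n)
                lam, sigma = 10.0 ** rng.uniform(-4, 0), rng.uniform(0.1, 2)
                model = io.fit_krls(x, y, kernel, sigma=sigma, lam=lam)
                a, b = brute_force_krls(x, y, kernel, sigma, lam)
                assert np.allclose(model.dual_coef_, a, atol=1e-8)
                assert model.offset_ == pytest.approx(b)

    def test_matches_sklearn_kernel_ridge(self):
        rng = np.random.default_rng(1)
        x, y = rng.uniform(0, 1, 40), rng.normal(0, 1, 40)
        sigma, lam = 0.3, 1e-3
        ours = io.fit_krls(x, y, "rbf", sigma=sigma, lam=lam)
        ref = KernelRidge(alpha=lam * 40, kernel="rbf", gamma=1 / sigma)
        ref.fit(x[:, None], y - y.mean())
        grid = np.linspace(0, 1, 17)
        assert np.allclose(ours.predict(grid),
                           ref.predict(grid[:, None]) + y.mean(), atol=1e-8)

    def test_huge_lambda_predicts_the_mean(self):
        x = np.array([0.0, 0.5, 1.0])
        y = np.array([1.0, 5.0, 3.0])
        model = io.fit_krls(x, y, "rbf", sigma=1.0, lam=1e12)
        assert np.allclose(model.predict([0.2, 0.9]), y.mean(), atol=1e-6)

    def test_interpolates_distinct_inputs_at_zero_lambda(self):
        x = np.array([0.0, 0.3, 0.7, 1.0])
        y = np.array([0.0, 2.0, -1.0, 4.0])
        model = io.fit_krls(x, y, "rbf", sigma=0.05, lam=0.0)
        assert np.allclose(model.predict(x), y, atol=1e-6)

    def test_linear_noiseless_line_recovered(self):
        x = np.linspace(-1, 1, 9)
        y = 2.5 * x
        model = io.fit_krls(x, y, "linear", lam=0.0)
        assert np.allclose(model.predict(x), y, atol=1e-8)

    def test_empty_prediction_input(self):
        model = io.fit_krls([0.0, 1.0], [1.0, 2.0], "rbf", sigma=1.0)
        assert model.predict(np.empty(0)).size == 0

    def test_training_mse_non_decreasing_in_lambda(self):
        rng = np.random.default_rng(2)
        x, y = rng.uniform(0, 1, 30), rng.normal(0, 1, 30)
        mses = []
        for lam in (1e-6, 1e-4, 1e-2, 1.0, 100.0):
            m = io.fit_krls(x, y, "rbf", sigma=0.2, lam=lam)
            mses.append(float(np.mean((m.predict(x) - y) ** 2)))
        assert all(b >= a - 1e-10 for a, b in zip(mses, mses[1:]))

    def test_sklearn_estimator_protocol(self):
        model = io.KRLSRegressor(kernel="linear", lam=0.5)
        params = model.get_params()
        assert params["kernel"] == "linear" and params["lam"] == 0.5
        cloned = clone(model).set_params(lam=0.1)
        assert cloned.get_params()["lam"] == 0.1


class TestHyperparameterSelection:
    def test_noiseless_linear_data_fit_well(self):
        # line through the origin after centering: exactly representable
        x = np.linspace(-1, 1, 30)
        y = 3.0 * x
        sigma, lam = io.select_hyperparameters(x, y, "linear", folds=5, seed=0)
        model = io.fit_krls(x, y, "linear", lam=lam)
        assert np.mean((model.predict(x) - y) ** 2) < 1e-4

    def test_grid_of_one_returned(self):
        x, y = np.linspace(0, 1, 12), np.linspace(0, 1, 12)
        sigma, lam = io.select_hyperparameters(
            x, y, "rbf", lam_grid=[0.5], sigma_grid=[2.0], folds=3, seed=0)
        assert (sigma, lam) == (2.0, 0.5)

    def test_pure_noise_selects_heavy_shrinkage(self):
        wins = 0
        lam_grid = np.logspace(-6, 2, 9)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x, y = rng.uniform(0, 1, 40), rng.normal(0, 1, 40)
            _, lam = io.select_hyperparameters(x, y, "rbf", folds=5, seed=seed)
            if lam >= lam_grid[-3]:
                wins += 1
        assert wins > 10

    def test_fewer_observations_than_folds_warns(self):
        x, y = np.arange(4.0), np.arange(4.0)
        with pytest.warns(UserWarning, match="reducing folds"):
            io.select_hyperparameters(x, y, "linear", folds=10, seed=0)


class TestMetrics:
    def test_accuracy_exact_and_rounded(self):
        truth = np.array([1, 2, 3, 4])
        assert io.accuracy_spike_count(truth, truth) == 1.0
        assert io.accuracy_spike_count(truth + 0.4, truth) == 1.0
        assert io.accuracy_spike_count(truth + 0.6, truth) == 0.0

    def test_accuracy_matches_brute_force(self):
        rng = np.random.default_rng(3)
        pred = rng.uniform(0, 6, 200)
        truth = rng.integers(0, 6, 200)
        brute = np.mean([int(round(p)) == t for p, t in zip(pred, truth)])
        assert io.accuracy_spike_count(pred, truth) == pytest.approx(brute)

    def test_chance_level_distinct_and_max_rules(self):
        counts = np.arange(1, 13)  # values 1..12 all seen in training
        assert io.chance_level(counts, "distinct") == pytest.approx(1 / 12)
        assert io.chance_level(counts, "max") == pytest.approx(1 / 12)
        assert io.chance_level([0, 3, 3, 7], "distinct") == pytest.approx(1 / 3)
        assert io.chance_level([5, 5, 5]) == pytest.approx(1.0)

    def test_nmse_identities(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 2, 50)
        assert io.nmse(np.full(50, y.mean()), y) == pytest.approx(1.0)
        assert io.nmse(y, y) == 0.0

    def test_nmse_matches_two_pass_computation(self):
        rng = np.random.default_rng(5)
        pred, y = rng.normal(0, 1, 80), rng.normal(0, 1, 80)
        direct = np.mean((pred - y) ** 2) / np.var(y)
        assert io.nmse(pred, y) == pytest.approx(direct, abs=1e-12)

    def test_nmse_zero_variance_undefined(self):
        with pytest.warns(UserWarning, match="variance"):
            assert np.isnan(io.nmse([1.0, 2.0], [3.0, 3.0]))


class TestCrossValidatedEvaluation:
    def test_channel_below_min_observations_excluded(self):
        rng = np.random.default_rng(6)
        data = {0: (rng.uniform(0, 1, 9), rng.normal(0, 1, 9)),
                1: (rng.uniform(0, 1, 30), rng.normal(0, 1, 30))}
        rep = io.cross_validated_evaluation(data, "linear", task="latency",
                                            seed=0)
        assert rep.excluded_channels == [0]
        assert list(rep.per_channel) == [1]

    def test_learnable_count_mapping_beats_chance(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.05, 1.0, 60)
        g = 6 * x**2 / (x**2 + 0.16)
        y = np.rint(g + rng.normal(0, 0.25, 60))
        rep = io.cross_validated_evaluation({0: (x, y)}, "rbf", task="count",
                                            seed=0)
        assert rep.per_channel[0] - rep.chance[0] > 0.3

    def test_unrelated_latency_gives_nmse_near_one(self):
        rng = np.random.default_rng(8)
        x = rng.choice([50.0, 100.0, 200.0, 500.0], 80)
        y = rng.normal(8.0, 1.0, 80)  # independent of the stimulus
        for kernel in ("rbf", "linear"):
            rep = io.cross_validated_evaluation({0: (x, y)}, kernel,
                                                task="latency", seed=0)
            assert rep.per_channel[0] > 0.8

    def test_report_reproducible_given_seed(self):
        rng = np.random.default_rng(9)
        x, y = rng.uniform(0, 1, 40), rng.integers(0, 5, 40).astype(float)
        a = io.cross_validated_evaluation({0: (x, y)}, "rbf", task="count",
                                          seed=3)
        b = io.cross_validated_evaluation({0: (x, y)}, "rbf", task="count",
                                          seed=3)
        assert a.per_channel == b.per_channel
        assert a.fold_assignments == b.fold_assignments

    def test_all_channels_excluded_warns_empty(self):
        with pytest.warns(UserWarning, match="excluded"):
            rep = io.cross_validated_evaluation(
                {0: (np.arange(3.0), np.arange(3.0))}, "linear",
                task="latency", seed=0)
        assert rep.per_channel == {}
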