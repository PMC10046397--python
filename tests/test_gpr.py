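"""Exponential-kernel GP regression: initialisation statistics, kernel
algebra, dense-solve oracle equivalence, fixed-kernel fine-tuning, and
parameter recovery on synthetic cohorts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from ppgbp.gpr import (
    PRETRAINED_KERNEL_SCALE,
    PRETRAINED_SIGNAL_STD,
    KernelParams,
    exp_kernel,
    finetune,
    fit,
    kernel_scale_search_interval,
    load_model,
    predict,
    predict_one,
    save_model,
    signal_std_init,
    xmax_range,
)
from ppgbp.pipeline import make_training_data


def _dense_gp_oracle(X, y, params, x_star):
    """Textbook GP posterior via explicit dense inverse (no caching, no tricks)."""
    K = params.signal_std**2 * np.exp(-cdist(X, X) / params.kernel_scale)
    K += (params.noise_std**2 + 1e-8 * params.signal_std**2) * np.eye(len(X))
    Kinv = np.linalg.inv(K)
    ks = params.signal_std**2 * np.exp(-cdist(np.atleast_2d(x_star), X) / params.kernel_scale)
    mu = float(np.mean(y)) + ks @ Kinv @ (y - np.mean(y))
    var = params.signal_std**2 + params.noise_std**2 - np.sum((ks @ Kinv) * ks, axis=1)
    return mu, np.sqrt(var)


class TestInitStatistics:
    def test_xmax_range_examples(self):
        assert xmax_range(np.zeros((4, 3))) == 0.0
        assert xmax_range(np.array([[0.0, 1.0], [1.0, 4.0]])) == 3.0
        assert xmax_range(np.array([[2.0, 5.0, 9.0]])) == 0.0  # single row

    def test_kernel_scale_interval_is_0p001_to_1_times_range(self):
        X = np.array([[0.0, 1.0], [1.0, 4.0]])
        assert kernel_scale_search_interval(X) == (0.003, 3.0)

    def test_signal_std_hand_values(self):
        assert signal_std_init(np.array([[1.0, 2.0, 3.0]])) == pytest.approx(1.0)
        assert signal_std_init(np.full((5, 2), 3.7)) == pytest.approx(0.0, abs=1e-12)

    def test_signal_std_homogeneous_in_scale(self):
        X = np.array([[1.0, 5.0], [2.0, 0.5]])
        assert signal_std_init(4.0 * X) == pytest.approx(4.0 * signal_std_init(X))
        assert signal_std_init(-2.0 * X) == pytest.approx(2.0 * signal_std_init(X))

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            xmax_range(np.empty((0, 3)))
        with pytest.raises(ValueError):
            signal_std_init(np.array([[1.0]]))


class TestKernel:
    def test_zero_distance_gives_signal_variance(self):
        p = KernelParams(2.0, 3.0, 1.0)
        x = np.arange(10.0)
        assert exp_kernel(x, x, p) == pytest.approx(9.0)

    def test_unit_scale_distance(self):
        p = KernelParams(kernel_scale=5.0, signal_std=2.0)
        assert exp_kernel(np.array([0.0]), np.array([5.0]), p) == pytest.approx(4.0 * np.exp(-1))

    def test_matches_direct_formula_on_random_pair(self):
        rng = np.random.default_rng(1)
        xi, xj = rng.normal(size=10), rng.normal(size=10)
        p = KernelParams(1.7, 2.2, 0.5)
        d = np.sqrt(np.sum((xi - xj) ** 2))
        assert exp_kernel(xi, xj, p) == pytest.approx(2.2**2 * np.exp(-d / 1.7), rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            exp_kernel(np.zeros(3), np.zeros(4), KernelParams(1.0, 1.0))

    def test_nonpositive_params_rejected(self):
        with pytest.raises(ValueError):
            KernelParams(0.0, 1.0, 1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_kernel_matrix_symmetric_positive_definite(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 4))
        p = KernelParams(float(rng.uniform(0.5, 5)), float(rng.uniform(0.5, 5)))
        K = p.signal_std**2 * np.exp(-cdist(X, X) / p.kernel_scale)
        np.testing.assert_allclose(K, K.T)
        w = np.linalg.eigvalsh(K + 1e-8 * p.signal_std**2 * np.eye(6))
        assert np.all(w > 0)


class TestFitPredict:
    def test_fixed_kernel_keeps_shipped_constants_exactly(self, small_cohort_features):
        m = fit(
            small_cohort_features,
            small_cohort_features.sbp,
            init=KernelParams(PRETRAINED_KERNEL_SCALE, PRETRAINED_SIGNAL_STD, 1.0),
            fix_kernel=True,
        )
        assert m.params.kernel_scale == 11.9
        assert m.params.signal_std == 9.6
        assert m.optimized == ("noise_std",)

    def test_full_fit_searches_all_three_hyperparameters(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        y = X[:, 0] * 2 + rng.normal(0, 0.1, 30)
        m = fit(X, y)
        assert m.optimized == ("kernel_scale", "signal_std", "noise_std")
        lo, hi = kernel_scale_search_interval(m.X_train)
        assert lo * 0.999 <= m.params.kernel_scale <= hi * 1.001

    def test_two_point_posterior_matches_2x2_solve(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([1.0, 3.0])
        m = fit(X, y, init=KernelParams(1.0, 1.0, 0.3), fix_kernel=True)
        mu, sd = predict(m, m.feat_mean + m.feat_std * m.X_train)  # training points
        oracle_mu, oracle_sd = _dense_gp_oracle(m.X_train, y, m.params, m.X_train)
        np.testing.assert_allclose(mu, oracle_mu, atol=1e-10)
        np.testing.assert_allclose(sd, oracle_sd, atol=1e-10)

    def test_constant_response_predicts_constant(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        m = fit(X, np.full(12, 42.0), init=KernelParams(2.0, 1.0, 0.1), fix_kernel=True)
        mu, _ = predict(m, X)
        np.testing.assert_allclose(mu, 42.0, atol=1e-6)

    @pytest.mark.parametrize("n", [3, 5, 10])
    def test_posterior_matches_dense_inverse_oracle(self, n):
        rng = np.random.default_rng(n)
        X = rng.normal(size=(n, 10))
        y = rng.normal(size=n) * 5 + 100
        params = KernelParams(3.0, 4.0, 0.7)
        m = fit(X, y, init=params, fix_kernel=True)
        q = rng.normal(size=(4, 10))
        mu, sd = predict(m, q)
        qs = m.standardize(q)
        oracle_mu, oracle_sd = _dense_gp_oracle(m.X_train, y, m.params, qs)
        np.testing.assert_allclose(mu, oracle_mu, rtol=1e-8, atol=1e-8)
        np.testing.assert_allclose(sd, oracle_sd, rtol=1e-8, atol=1e-8)

    def test_interpolates_training_point_at_small_noise(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 2))
        y = 100 + 3 * X[:, 0]
        m = fit(X, y, init=KernelParams(2.0, 5.0, 1e-3), fix_kernel=True)
        mu, _ = predict(m, X)
        np.testing.assert_allclose(mu, y, atol=1e-2)

    def test_far_query_reverts_to_prior(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6) + 50
        m = fit(X, y, init=KernelParams(1.5, 2.0, 0.5), fix_kernel=True)
        far = m.feat_mean + m.feat_std * 1e6
        mu, sd = predict_one(m, far)
        assert mu == pytest.approx(m.mean_const, abs=1e-6)
        assert sd == pytest.approx(np.hypot(m.params.signal_std, m.params.noise_std), abs=1e-6)

    def test_matches_sklearn_matern_half(self):
        """Independent cross-check: Matérn ν=1/2 in scikit-learn is the same
        exponential covariance; posteriors must agree."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import ConstantKernel, Matern

        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 3))
        y = 10 * np.sin(X[:, 0]) + rng.normal(0, 0.2, 15)
        params = KernelParams(2.0, 3.0, 0.4)
        m = fit(X, y, init=params, fix_kernel=True)
        kern = ConstantKernel(9.0, constant_value_bounds="fixed") * Matern(
            length_scale=2.0, length_scale_bounds="fixed", nu=0.5
        )
        sk = GaussianProcessRegressor(
            kernel=kern, alpha=m.params.noise_std**2, optimizer=None, normalize_y=False
        )
        sk.fit(m.X_train, y - m.mean_const)
        q = rng.normal(size=(5, 3))
        mu_sk = sk.predict(m.standardize(q)) + m.mean_const
        mu, _ = predict(m, q)
        np.testing.assert_allclose(mu, mu_sk, atol=1e-6)


class TestFinetune:
    def test_empty_new_data_returns_pretrained_unchanged(self, small_cohort_features):
        m = fit(small_cohort_features, small_cohort_features.sbp)
        out = finetune(m, np.empty((0, 10)), np.empty(0))
        assert out is m

    def test_kernel_constants_survive_finetuning(self, small_cohort_features):
        fm = small_cohort_features
        pre = fit(fm, fm.sbp, init=KernelParams(11.9, 9.6, 1.0), fix_kernel=True)
        rng = np.random.default_rng(0)
        X_new = fm.X + rng.normal(0, 1e-3, fm.X.shape)
        tuned = finetune(pre, X_new, fm.sbp)
        assert tuned.params.kernel_scale == 11.9
        assert tuned.params.signal_std == 9.6
        assert pre.params.kernel_scale == 11.9  # pretrained untouched

    def test_equivalent_to_fresh_fixed_kernel_fit(self, small_cohort_features):
        fm = small_cohort_features
        pre = fit(fm, fm.sbp, init=KernelParams(11.9, 9.6, 1.0), fix_kernel=True)
        rng = np.random.default_rng(1)
        X_new = fm.X * (1 + rng.normal(0, 0.01, fm.X.shape))
        y_new = fm.sbp + 1.0
        tuned = finetune(pre, X_new, y_new)
        fresh = fit(X_new, y_new, init=pre.params, fix_kernel=True)
        q = fm.X[:3]
        np.testing.assert_allclose(predict(tuned, q)[0], predict(fresh, q)[0], atol=1e-10)

    def test_finetuning_searches_noise_only(self, small_cohort_features):
        fm = small_cohort_features
        pre = fit(fm, fm.dbp, init=KernelParams(11.9, 9.6, 1.0), fix_kernel=True)
        tuned = finetune(pre, fm.X, fm.dbp)
        assert tuned.optimized == ("noise_std",)


class TestSerialization:
    def test_save_load_round_trip(self, small_cohort_features, tmp_path):
        fm = small_cohort_features
        m = fit(fm, fm.sbp, init=KernelParams(11.9, 9.6, 1.0), fix_kernel=True)
        save_model(m, tmp_path / "m.json")
        m2 = load_model(tmp_path / "m.json")
        q = fm.X[:3]
        np.testing.assert_allclose(predict(m, q)[0], predict(m2, q)[0], atol=1e-12)
        assert m2.params == m.params


class TestParameterRecovery:
    def test_cohort_rmse_within_5mmhg_and_iso1(self):
        """200 training / 100 test windows from the study-condition generator:
        held-out RMSE ≤ 5 mmHg per target, errors within ISO criterion 1."""
        root = np.random.SeedSequence(0)
        ss_tr, ss_te = root.spawn(2)
        train = make_training_data(100, ss_tr)
        test = make_training_data(50, ss_te)
        assert train.n == 200 and test.n == 100
        for target in ("sbp", "dbp"):
            m = fit(
                train,
                getattr(train, target),
                init=KernelParams(PRETRAINED_KERNEL_SCALE, PRETRAINED_SIGNAL_STD, 1.0),
                fix_kernel=True,
            )
            err = predict(m, test.X)[0] - getattr(test, target)
            assert np.sqrt(np.mean(err**2)) <= 5.0, target
            assert abs(np.mean(err)) <= 5.0 and np.std(err, ddof=1) <= 8.0, target
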