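import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LinearRegression

from ramanscreen.chemometrics import (
    ACTIVATION_ORDER,
    ANNSearchRegressor,
    DegenerateTargetError,
    PCAScores,
    PLSCalibrator,
    fit_pca_scores,
    predict_ann,
    split_calibration,
)


class TestSplitCalibration:
    def test_default_study_splits_52_13(self, default_study):
        cal, val = split_calibration(default_study.dataset, 0.8, seed=3)
        assert len(cal) == 52 and len(val) == 13

    def test_seed_reproducible(self, small_study):
        a = split_calibration(small_study.dataset, 0.8, seed=5)
        b = split_calibration(small_study.dataset, 0.8, seed=5)
        assert a == b

    def test_every_run_present_in_calibration(self, small_study):
        cal, _ = split_calibration(small_study.dataset, 0.8, seed=1)
        runs = {small_study.references.loc[s, "run_id"] for s in cal}
        assert runs == set(small_study.references["run_id"])


class TestPLS:
    def _noise_free(self, n=40, p=60, seed=0):
        # one dominant spectral channel carries the whole signal
        rng = np.random.default_rng(seed)
        X = 0.01 * rng.normal(size=(n, p))
        X[:, 5] = rng.normal(size=n)
        y = 3.0 * X[:, 5] + 1.0
        return X, y

    def test_rank_one_signal_needs_one_lv(self):
        X, y = self._noise_free()
        m = PLSCalibrator(max_lv=5).fit(X, y)
        assert m.n_lv_ == 1
        assert m.r2cum_[0] >= 0.999

    def test_r2cum_nondecreasing_and_q2_below_r2(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 30))
        y = X[:, :3] @ [1.0, -2.0, 0.5] + 0.3 * rng.normal(size=40)
        m = PLSCalibrator(max_lv=6).fit(X, y)
        assert np.all(np.diff(m.r2cum_) >= -1e-10)
        assert np.all(m.q2cum_ <= m.r2cum_ + 1e-8)

    def test_permutation_null_gives_near_zero_q2(self):
        q2 = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 50))
            y = rng.normal(size=30)  # independent of X
            m = PLSCalibrator(max_lv=3, random_state=seed).fit(X, y)
            q2.append(m.q2cum_[m.n_lv_ - 1])
        assert np.mean(q2) <= 0.05

    def test_predictions_match_sklearn_pls(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 80))
        y = rng.normal(size=30)
        Xt = rng.normal(size=(10, 80))
        for k in (1, 3, 5):
            m = PLSCalibrator(max_lv=k, q2_gain_threshold=-np.inf).fit(X, y)
            assert m.n_lv_ == k
            sk = PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(m.predict(Xt), sk.predict(Xt).ravel(),
                                       atol=1e-8)

    def test_full_rank_pls_reproduces_ols(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 5))
        y = X @ [1, -1, 2, 0.5, -0.2] + 0.1 * rng.normal(size=40)
        m = PLSCalibrator(max_lv=5, q2_gain_threshold=-np.inf).fit(X, y)
        ols = LinearRegression().fit(X, y)
        np.testing.assert_allclose(m.predict(X), ols.predict(X), atol=1e-6)

    def test_predict_at_calibration_mean_returns_y_mean(self):
        X, y = self._noise_free()
        m = PLSCalibrator(max_lv=3).fit(X, y)
        assert m.predict(X.mean(axis=0)[None, :])[0] == pytest.approx(y.mean())

    def test_zero_variance_target_rejected(self):
        X = np.random.default_rng(4).normal(size=(20, 10))
        with pytest.raises(DegenerateTargetError):
            PLSCalibrator().fit(X, np.ones(20))


class TestPCAScores:
    def test_rank_two_matrix_needs_two_pcs(self):
        rng = np.random.default_rng(5)
        X = np.outer(rng.normal(size=30), rng.normal(size=40)) \
            + np.outer(rng.normal(size=30), rng.normal(size=40))
        basis = fit_pca_scores(X, variance_target=0.999)
        assert basis.n_pc_ == 2

    def test_scores_centred_and_reconstruction_error_matches(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 40))
        basis = PCAScores(variance_target=0.9).fit(X)
        scores = basis.transform(X)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)
        Xc = X - basis.mean_
        recon = scores @ basis.components_
        rel = np.sum((Xc - recon) ** 2) / np.sum(Xc**2)
        assert rel == pytest.approx(
            1.0 - basis.explained_variance_ratio_.sum(), abs=1e-8)


class TestANN:
    def test_linear_target_won_by_near_perfect_network(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 3))
        y = X[:, 0]
        m = ANNSearchRegressor(random_state=0).fit(X, y)
        assert m.correlations_[1] >= 0.99

    def test_grid_cardinality_and_split_fractions(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 2))
        m = ANNSearchRegressor(random_state=1, max_epochs=50).fit(
            X, X[:, 0] + X[:, 1])
        assert m.n_networks_ == 25 * (2 + 1)
        assert len(m.train_idx_) == 28  # 70 % of 40
        assert len(m.test_idx_) == len(m.val_idx_) == 6

    def test_search_is_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 2))
        y = np.sin(X[:, 0])
        a = ANNSearchRegressor(random_state=5, max_epochs=60).fit(X, y)
        b = ANNSearchRegressor(random_state=5, max_epochs=60).fit(X, y)
        assert (a.n_hidden_, a.hidden_activation_, a.output_activation_) == \
               (b.n_hidden_, b.hidden_activation_, b.output_activation_)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_forward_pass_matches_manual_matrices(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 2))
        y = X[:, 0] - 0.5 * X[:, 1]
        m = ANNSearchRegressor(random_state=2, max_epochs=40).fit(X, y)
        net = m.network_
        Z = (X - m.x_center_) / m.x_scale_
        from ramanscreen.chemometrics import ACTIVATIONS
        h = ACTIVATIONS[net.hidden_act][0](Z @ net.W1 + net.b1)
        out = ACTIVATIONS[net.out_act][0](h @ net.W2 + net.b2).ravel()
        np.testing.assert_allclose(m.predict(X),
                                   out * m.y_scale_ + m.y_center_, atol=1e-10)

    def test_projection_prediction_pipeline(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 30))
        y = X[:, 0]
        basis = fit_pca_scores(X, variance_target=0.9, n_pc_max=3)
        m = ANNSearchRegressor(random_state=3, max_epochs=60).fit(
            basis.transform(X), y)
        np.testing.assert_allclose(predict_ann(m, basis, X),
                                   m.predict(basis.transform(X)))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ANNSearchRegressor().fit(np.ones((5, 2)), np.arange(5.0))

    def test_activation_order_is_canonical(self):
        assert ACTIVATION_ORDER == ("identity", "logistic", "tanh",
                                    "exponential", "sine")
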