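"""NIPALS PLS core: fit/predict identities, oracles, outlier screening."""

import numpy as np
import pytest

from nirsalt import pls
from nirsalt.exceptions import ValidationError


def random_problem(seed, n=20, p=8, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestFit:
    def test_single_informative_column_perfect_fit(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 5))
        y = 2.0 + 3.0 * X[:, 2]
        X[:, [0, 1, 3, 4]] = rng.normal(size=(15, 4)) * 0  # only col 2 varies
        model = pls.fit_pls(X, y, 1)
        np.testing.assert_allclose(pls.predict(model, X), y, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_rank_equals_least_squares(self, seed):
        X, y = random_problem(seed, noise=0.3)
        model = pls.fit_pls(X, y, 8)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        np.testing.assert_allclose(model.coef, beta, atol=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_sklearn_nipals(self, seed):
        sk = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_problem(seed, n=30, p=10, noise=0.5)
        for a in (2, 4):
            model = pls.fit_pls(X, y, a)
            ref = sk.PLSRegression(n_components=a, scale=False).fit(X, y)
            np.testing.assert_allclose(
                pls.predict(model, X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_duplicated_column_rank_cap_matches_reduced_fit(self):
        X, y = random_problem(3, noise=0.2)
        X_dup = np.hstack([X, X[:, [0]]])
        model = pls.fit_pls(X_dup, y, 9)  # rank is only 8
        assert model.n_components <= 8
        model_red = pls.fit_pls(X, y, 8)
        np.testing.assert_allclose(
            pls.predict(model, X_dup), pls.predict(model_red, X), atol=1e-7
        )

    def test_over_cap_request_names_maximum(self):
        X, y = random_problem(0, n=5, p=8)
        with pytest.raises(ValidationError, match=r"\[1, 4\]"):
            pls.fit_pls(X, y, 5)

    def test_constant_response_rejected(self):
        X, _ = random_problem(0)
        with pytest.raises(ValidationError, match="variance"):
            pls.fit_pls(X, np.ones(20), 2)

    def test_scores_orthogonal(self):
        X, y = random_problem(7, n=40, p=12, noise=0.5)
        model = pls.fit_pls(X, y, 6)
        G = model.scores.T @ model.scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)

    def test_training_rmse_never_increases_with_components(self):
        X, y = random_problem(9, n=25, p=10, noise=1.0)
        rmse = []
        for a in range(1, 9):
            model = pls.fit_pls(X, y, a)
            rmse.append(np.sqrt(np.mean((pls.predict(model, X) - y) ** 2)))
        assert all(b <= a + 1e-12 for a, b in zip(rmse, rmse[1:]))


class TestPredict:
    def test_mean_row_predicts_mean_response(self):
        X, y = random_problem(1, noise=0.5)
        model = pls.fit_pls(X, y, 3)
        assert pls.predict(model, X.mean(axis=0))[0] == pytest.approx(y.mean())

    def test_shifted_row_responds_linearly(self):
        X, y = random_problem(2, noise=0.5)
        model = pls.fit_pls(X, y, 4)
        delta = np.zeros(8)
        delta[3] = 0.7
        base = pls.predict(model, X[[5]])[0]
        shifted = pls.predict(model, X[[5]] + delta)[0]
        assert shifted - base == pytest.approx(delta @ model.coef)

    def test_column_mismatch_rejected(self):
        X, y = random_problem(0)
        model = pls.fit_pls(X, y, 2)
        with pytest.raises(ValidationError, match="mismatch"):
            pls.predict(model, X[:, :5])


class TestMahalanobis:
    def test_training_mean_squared_distance_identity(self):
        X, y = random_problem(4, n=30, p=6, noise=0.5)
        model = pls.fit_pls(X, y, 2)
        d = pls.mahalanobis_distances(model, X)
        n = X.shape[0]
        assert np.mean(d**2) == pytest.approx(2 * (n - 1) / n)

    def test_centroid_has_zero_distance(self):
        X, y = random_problem(5, noise=0.3)
        model = pls.fit_pls(X, y, 3)
        assert pls.mahalanobis_distances(model, X.mean(axis=0))[0] == pytest.approx(0, abs=1e-8)

    def test_matches_brute_force_quadratic_form(self):
        X, y = random_problem(6, n=5, p=4, noise=0.4)
        model = pls.fit_pls(X, y, 2)
        T = model.scores
        S_inv = np.linalg.inv(np.cov(T, rowvar=False, ddof=1))
        expected = np.sqrt([t @ S_inv @ t for t in T])
        np.testing.assert_allclose(pls.mahalanobis_distances(model, X), expected, atol=1e-10)


class TestRemoveOutliers:
    def test_clean_data_untouched(self):
        X, y = random_problem(8, n=60, p=6, noise=0.3)
        Xf, yf, report = pls.remove_outliers(X, y, 3)
        assert report.removed_ids == []
        assert Xf.shape == X.shape

    def test_planted_outlier_removed(self):
        X, y = random_problem(10, n=40, p=6, noise=0.3)
        model = pls.fit_pls(X, y, 3)
        # displace one sample far along the dominant weight direction
        X_bad = X.copy()
        X_bad[7] += 40 * np.std(model.scores[:, 0]) * model.weights[:, 0]
        _, _, report = pls.remove_outliers(
            X_bad, y, 3, sample_ids=[f"s{i}" for i in range(40)]
        )
        assert report.removed_ids == ["s7"]

    def test_infinite_threshold_is_identity(self):
        X, y = random_problem(12, n=30, p=5, noise=0.3)
        Xf, _, report = pls.remove_outliers(X, y, 3, threshold_rule=np.inf)
        assert Xf.shape == X.shape and report.removed_ids == []

    def test_mass_removal_aborts(self):
        X, y = random_problem(13, n=20, p=5, noise=0.3)
        with pytest.raises(ValidationError, match="aborting"):
            pls.remove_outliers(X, y, 3, threshold_rule=1e-6)


class TestSelectComponents:
    def test_two_latent_directions_found(self):
        rng = np.random.default_rng(21)
        T = rng.normal(size=(80, 2))
        load = rng.normal(size=(2, 30))
        X = T @ load + 0.01 * rng.normal(size=(80, 30))
        y = T @ [1.0, -0.5] + 0.01 * rng.normal(size=80)
        chosen, curve = pls.select_components(X, y, 8, "loo")
        assert chosen == 2
        assert curve.shape == (8,)

    def test_pure_noise_floors_at_one(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        chosen, _ = pls.select_components(X, y, 6, "loo")
        assert chosen == 1

    def test_max_one_returns_one(self):
        X, y = random_problem(0)
        chosen, curve = pls.select_components(X, y, 1, "loo")
        assert chosen == 1 and curve.size == 1


class TestSerialization:
    def test_round_trip(self, tmp_path):
        X, y = random_problem(30, noise=0.4)
        model = pls.fit_pls(X, y, 3, sample_ids=[f"s{i}" for i in range(20)])
        path = tmp_path / "model.txt"
        pls.save_model(model, path)
        back = pls.load_model(path)
        np.testing.assert_allclose(back.coef, model.coef)
        np.testing.assert_allclose(pls.predict(back, X), pls.predict(model, X))
        assert back.training_meta["sample_ids"] == model.training_meta["sample_ids"]

    def test_format_versioned(self, tmp_path):
        path = tmp_path / "bogus.txt"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValidationError, match="format"):
            pls.load_model(path)
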