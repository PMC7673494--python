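"""Contracts of the seven suitability models.

Each model has an independent oracle: rank arithmetic for BIOCLIM,
brute-force Gower similarity for Domain, statsmodels IRLS for the GLM,
and a derivative-free optimizer of the same penalized objective for
MaxEnt.
"""

import numpy as np
import pytest

from conftest import make_grid
from sdmconnect import models as M
from sdmconnect.raster import RasterStack
from sdmconnect.synthetic import make_environment


def _names(p):
    return [f"v{i}" for i in range(p)]


class TestBioclim:
    def test_training_median_scores_one(self, rng):
        X = rng.normal(size=(40, 3))
        m = M.fit_bioclim(X, _names(3))
        med = np.median(X, axis=0)
        assert m.predict(med)[0] == pytest.approx(1.0, abs=0.05)

    def test_outside_envelope_scores_zero(self, rng):
        X = rng.normal(size=(20, 3))
        m = M.fit_bioclim(X, _names(3))
        far = X.max(axis=0) + 10
        assert m.predict(far)[0] == 0.0

    def test_rank_arithmetic_univariate(self):
        train = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0], [7.0]])
        m = M.fit_bioclim(train, ["v"])
        # x at the 2nd order statistic: p = (1 + 0.5)/7
        p = 1.5 / 7
        assert m.predict([[2.0]])[0] == pytest.approx(2 * min(p, 1 - p))

    def test_invariant_under_monotone_transform(self, rng):
        X = rng.normal(size=(30, 2))
        Xq = rng.normal(size=(50, 2))
        m1 = M.fit_bioclim(X, _names(2))
        f = lambda Z: np.column_stack([np.exp(Z[:, 0]), Z[:, 1] ** 3])
        m2 = M.fit_bioclim(f(X), _names(2))
        np.testing.assert_allclose(m1.predict(Xq), m2.predict(f(Xq)), atol=1e-12)

    def test_min_presences(self):
        with pytest.raises(ValueError, match="5"):
            M.fit_bioclim(np.zeros((4, 2)), _names(2))


class TestDomain:
    def test_training_point_scores_one(self, rng):
        X = rng.normal(size=(10, 4))
        m = M.fit_domain(X, _names(4))
        assert m.predict(X[3])[0] == pytest.approx(1.0)

    def test_full_range_away_scores_zero(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        m = M.fit_domain(X, _names(2))
        assert m.predict([[2.0, 2.0]])[0] == pytest.approx(0.0)

    def test_bruteforce_gower_oracle(self, rng):
        X = rng.normal(size=(10, 3))
        m = M.fit_domain(X, _names(3))
        ranges = X.max(axis=0) - X.min(axis=0)
        Q = rng.normal(size=(25, 3))
        expect = np.array(
            [
                max(1 - np.mean(np.abs(q - t) / ranges) for t in X)
                for q in Q
            ]
        )
        np.testing.assert_allclose(m.predict(Q), np.clip(expect, 0, 1), atol=1e-12)

    def test_invariant_under_affine_transform(self, rng):
        X = rng.normal(size=(12, 2))
        Q = rng.normal(size=(20, 2))
        a, b = np.array([3.0, -0.5]), np.array([10.0, 2.0])
        m1 = M.fit_domain(X, _names(2))
        m2 = M.fit_domain(X * a + b, _names(2))
        np.testing.assert_allclose(m1.predict(Q), m2.predict(Q * a + b), atol=1e-9)

    def test_zero_range_variable_warned(self, rng):
        X = rng.normal(size=(8, 2))
        X[:, 1] = 5.0
        with pytest.warns(UserWarning, match="zero-range"):
            M.fit_domain(X, _names(2))


class TestOneClassSVM:
    def test_centroid_outscores_far_point(self, rng):
        X = rng.normal(size=(100, 2))
        m = M.fit_ocsvm(X, _names(2))
        center = X.mean(axis=0, keepdims=True)
        far = center + 10 * X.std(axis=0)
        assert m.predict(center)[0] >= m.predict(far)[0]

    def test_nu_bounds_training_outliers(self, rng):
        X = rng.normal(size=(100, 2))
        m = M.fit_ocsvm(X, _names(2), nu=0.1)
        raw = M._ocsvm_raw(m, X)
        assert (raw < 0).sum() <= 10 + 5

    def test_duplication_invariance(self, rng):
        X = rng.normal(size=(30, 2))
        Q = rng.normal(size=(15, 2))
        m1 = M.fit_ocsvm(X, _names(2))
        m2 = M.fit_ocsvm(np.vstack([X, X]), _names(2))
        np.testing.assert_allclose(m1.predict(Q), m2.predict(Q), atol=1e-6)


class TestGLM:
    def test_null_slope_recovery(self, rng):
        X = rng.normal(size=(5000, 1))
        y = rng.integers(0, 2, 5000)
        m = M.fit_glm(X, y, ["noise"])
        assert abs(m.params["beta"][1]) < 0.1

    def test_parameter_recovery(self, rng):
        beta_true = np.array([-1.0, 2.0])
        X = rng.normal(size=(2000, 1))
        p = 1 / (1 + np.exp(-(beta_true[0] + beta_true[1] * X[:, 0])))
        y = (rng.random(2000) < p).astype(int)
        m = M.fit_glm(X, y, ["v"])
        np.testing.assert_allclose(m.params["beta"], beta_true, atol=0.2)

    def test_matches_statsmodels_irls(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(300, 3))
        y = (rng.random(300) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
        ours = M.fit_glm(X, y, _names(3))
        Z = ours.standardizer.transform(X)
        ref = sm.GLM(y, sm.add_constant(Z), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(ours.params["beta"], ref.params, atol=1e-6)

    def test_intercept_only_prevalence(self):
        X = np.zeros((100, 1))
        y = np.r_[np.ones(30), np.zeros(70)].astype(int)
        m = M.fit_glm(X, y, ["flat"])
        assert m.predict(np.zeros((1, 1)))[0] == pytest.approx(0.30, abs=1e-6)

    def test_separation_triggers_ridge(self):
        X = np.r_[np.linspace(-2, -1, 20), np.linspace(1, 2, 20)].reshape(-1, 1)
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        with pytest.warns(UserWarning, match="separation"):
            m = M.fit_glm(X, y, ["v"])
        assert m.params["separated"]
        assert np.isfinite(m.params["beta"]).all()


def _maxent_objective(eta, Fb, fbar, beta):
    u = Fb @ eta
    logZ = np.log(np.mean(np.exp(u - u.max()))) + u.max()
    return logZ - eta @ fbar + beta * np.abs(eta).sum()


class TestMaxent:
    def test_null_truth_gives_uniform_density(self, rng):
        # presences drawn from the background distribution itself
        Xb = rng.normal(size=(300, 2))
        Xp = Xb[rng.choice(300, 60, replace=False)]
        m = M.fit_maxent(Xp, Xb, _names(2))
        assert np.abs(m.params["eta"]).max() < 0.25

    def test_monotone_in_single_linear_feature(self, rng):
        Xb = rng.normal(size=(400, 1))
        Xp = Xb[Xb[:, 0] > 0.5].reshape(-1, 1)  # presences at high values
        m = M.fit_maxent(Xp, Xb, ["v"], features=("linear",))
        grid = np.linspace(-2, 2, 50).reshape(-1, 1)
        s = m.predict(grid)
        assert (np.diff(s) >= -1e-12).all() and s[-1] > s[0]

    def test_matches_independent_optimizer_on_tiny_instance(self, rng):
        from scipy.optimize import minimize

        Xb = rng.normal(size=(20, 1))
        Xp = Xb[Xb[:, 0] > 0].reshape(-1, 1)
        beta = 0.05
        m = M.fit_maxent(Xp, Xb, ["v"], beta=beta)
        std = m.standardizer
        Fb = M._maxent_features(std.transform(Xb), ("linear", "quadratic"))
        Fp = M._maxent_features(std.transform(Xp), ("linear", "quadratic"))
        fbar = Fp.mean(axis=0)
        # derivative-free minimization of the same penalized objective
        ref = minimize(
            _maxent_objective,
            x0=np.zeros(2),
            args=(Fb, fbar, beta),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        ours = _maxent_objective(m.params["eta"], Fb, fbar, beta)
        assert ours <= ref.fun + 1e-8
        np.testing.assert_allclose(m.params["eta"], ref.x, atol=1e-4)

    def test_presence_mean_score_convention(self, rng):
        Xb = rng.normal(size=(200, 2))
        Xp = Xb[:40] + 0.5
        m = M.fit_maxent(Xp, Xb, _names(2))
        assert m.predict(Xp).mean() == pytest.approx(0.5, abs=1e-3)

    def test_nonfinite_rejected(self):
        X = np.array([[np.nan, 1.0]])
        with pytest.raises(ValueError, match="finite"):
            M.fit_maxent(X, np.zeros((20, 2)), _names(2))


class TestSvmAnn:
    def _blobs(self, rng, n=120):
        X0 = rng.normal(loc=(-2, -2), scale=0.4, size=(n // 2, 2))
        X1 = rng.normal(loc=(2, 2), scale=0.4, size=(n // 2, 2))
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        return X, y

    def test_separable_blobs_perfect_heldout(self, rng):
        X, y = self._blobs(rng)
        Xq, yq = self._blobs(np.random.default_rng(99))
        for fit in (M.fit_svm, M.fit_ann):
            m = fit(X, y, _names(2))
            acc = ((m.predict(Xq) > 0.5).astype(int) == yq).mean()
            assert acc == 1.0

    def test_xor_capacity_contrast(self, rng):
        n = 400
        X = rng.uniform(-1, 1, size=(n, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        ann = M.fit_ann(X, y, _names(2), hidden=8, epochs=2000, seed=0)
        glm = M.fit_glm(X, y, _names(2))
        Xq = rng.uniform(-1, 1, size=(500, 2))
        yq = ((Xq[:, 0] > 0) ^ (Xq[:, 1] > 0)).astype(int)
        acc_ann = ((ann.predict(Xq) > 0.5).astype(int) == yq).mean()
        acc_glm = ((glm.predict(Xq) > 0.5).astype(int) == yq).mean()
        assert acc_ann > 0.9
        assert acc_glm < 0.7  # a linear model cannot express XOR

    def test_ann_deterministic_given_seed(self, rng):
        X, y = self._blobs(rng)
        m1 = M.fit_ann(X, y, _names(2), seed=5, epochs=50)
        m2 = M.fit_ann(X, y, _names(2), seed=5, epochs=50)
        np.testing.assert_array_equal(m1.params["w0"], m2.params["w0"])
        np.testing.assert_array_equal(m1.params["w1"], m2.params["w1"])

    def test_row_order_invariance(self, rng):
        X, y = self._blobs(rng)
        perm = rng.permutation(len(y))
        Q = rng.normal(size=(30, 2))
        for fit in (M.fit_svm, M.fit_ann):
            m1 = fit(X, y, _names(2))
            m2 = fit(X[perm], y[perm], _names(2))
            np.testing.assert_allclose(m1.predict(Q), m2.predict(Q), atol=1e-9)


class TestPredictRaster:
    def test_constant_stack_constant_map(self, rng):
        X = rng.normal(size=(30, 2))
        m = M.fit_bioclim(X, ["a", "b"])
        s = RasterStack(
            {
                "a": make_grid(np.full((6, 6), X[:, 0].mean()), name="a"),
                "b": make_grid(np.full((6, 6), X[:, 1].mean()), name="b"),
            }
        )
        out = M.predict_raster(m, s)
        assert np.unique(out.values).size == 1

    def test_domain_self_similarity_at_training_cell(self):
        s = make_environment(20, 20, 3, seed=4)
        X = s.env_matrix()[:10]
        m = M.fit_domain(X, s.names)
        out = M.predict_raster(m, s)
        r, c = 0, 0  # first valid cell corresponds to first row
        assert out.values[r, c] == pytest.approx(1.0)

    def test_extraction_consistency(self, rng):
        s = make_environment(15, 15, 2, seed=6)
        X = s.env_matrix()[:20]
        m = M.fit_bioclim(X, s.names)
        out = M.predict_raster(m, s)
        xs, ys, expect = [], [], []
        for r, c in [(2, 3), (7, 11), (14, 0)]:
            x, y = s.template.cell_center(r, c)
            xs.append(x)
            ys.append(y)
        vec = m.predict(s.extract(xs, ys))
        got = [out.values[s.template.cell_index(x, y)] for x, y in zip(xs, ys)]
        np.testing.assert_allclose(got, vec, atol=1e-12)

    def test_missing_layer_named(self, rng):
        m = M.fit_bioclim(rng.normal(size=(10, 2)), ["a", "zz"])
        s = RasterStack({"a": make_grid(np.zeros((4, 4)), name="a")})
        with pytest.raises(KeyError, match="zz"):
            M.predict_raster(m, s)


class TestSerialization:
    @pytest.mark.parametrize("kind", ["bioclim", "domain", "ocsvm", "glm", "maxent", "svm", "ann"])
    def test_json_roundtrip_preserves_predictions(self, kind, rng, tmp_path):
        X = rng.normal(size=(40, 2))
        y = (X.sum(axis=1) > 0).astype(int)
        names = _names(2)
        fitters = {
            "bioclim": lambda: M.fit_bioclim(X, names),
            "domain": lambda: M.fit_domain(X, names),
            "ocsvm": lambda: M.fit_ocsvm(X, names),
            "glm": lambda: M.fit_glm(X, y, names),
            "maxent": lambda: M.fit_maxent(X[y == 1], X, names),
            "svm": lambda: M.fit_svm(X, y, names),
            "ann": lambda: M.fit_ann(X, y, names, epochs=50),
        }
        m = fitters[kind]()
        p = M.save_model(m, tmp_path / f"{kind}.json")
        back = M.load_model(p)
        Q = rng.normal(size=(25, 2))
        np.testing.assert_allclose(m.predict(Q), back.predict(Q), atol=1e-12)

    def test_scores_bounded_all_models(self, rng):
        X = rng.normal(size=(50, 2))
        y = (X[:, 0] > 0).astype(int)
        names = _names(2)
        Q = rng.normal(scale=5, size=(200, 2))
        for m in [
            M.fit_bioclim(X, names),
            M.fit_domain(X, names),
            M.fit_ocsvm(X, names),
            M.fit_glm(X, y, names),
            M.fit_maxent(X[y == 1], X, names),
            M.fit_svm(X, y, names),
            M.fit_ann(X, y, names, epochs=50),
        ]:
            s = m.predict(Q)
            assert (s >= 0).all() and (s <= 1).all()
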