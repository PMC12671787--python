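"""Global and geographically weighted logistic regression."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import expit

from droughtfire import synthetic
from droughtfire.gwlr import (
    aicc,
    bisquare_weights,
    fit_glr,
    fit_gwlr,
    great_circle_distance,
    pairwise_distances,
    predict,
    select_bandwidth,
)


class TestDistance:
    def test_identity_and_symmetry(self, rng):
        assert great_circle_distance(10.0, 20.0, 10.0, 20.0) == 0.0
        lons = rng.uniform(-180, 180, 100)
        lats = rng.uniform(-89, 89, 100)
        d_ab = great_circle_distance(lons[:50], lats[:50], lons[50:], lats[50:])
        d_ba = great_circle_distance(lons[50:], lats[50:], lons[:50], lats[:50])
        assert np.allclose(d_ab, d_ba)
        assert np.all(d_ab >= 0)

    def test_one_degree_longitude_at_equator(self):
        # closed form: 2 pi R / 360
        expected = 2 * np.pi * 6371.0 / 360
        assert great_circle_distance(0.0, 0.0, 1.0, 0.0) == pytest.approx(expected, abs=0.01)
        assert expected == pytest.approx(111.19, abs=0.01)

    def test_bad_latitude_rejected(self):
        with pytest.raises(ValueError):
            great_circle_distance(0.0, 91.0, 0.0, 0.0)


class TestKernel:
    def test_closed_form_weights(self):
        # distances [0, b/2, b] with N=3 makes the bandwidth exactly b
        w = bisquare_weights(np.array([0.0, 5.0, 10.0]), 3)
        assert w[0] == 1.0
        assert w[1] == pytest.approx(0.5625)
        assert w[2] == 0.0

    def test_bandwidth_larger_than_sample_rejected(self):
        with pytest.raises(ValueError):
            bisquare_weights(np.array([0.0, 1.0, 2.0]), 4)

    def test_matrix_diagonal_is_one(self, grid5):
        d = pairwise_distances(grid5.cells[["lon", "lat"]].to_numpy())
        w = bisquare_weights(d, 6)
        assert np.allclose(np.diag(w), 1.0)
        assert np.all((w >= 0) & (w <= 1))


class TestAicc:
    def test_printed_formula_example(self):
        aic, acc = aicc(-100.0, 5, 50)
        assert aic == 210.0
        assert acc == pytest.approx(210.0 + 60.0 / 44.0)

    def test_zero_parameter_and_large_sample_limits(self):
        aic, acc = aicc(-10.0, 0, 50)
        assert acc == aic
        aic, acc = aicc(-10.0, 3, 10**9)
        assert acc == pytest.approx(aic, abs=1e-6)

    def test_domain_guard(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


def _simulate(rng, n, beta, trials=25):
    X = rng.normal(size=(n, len(beta) - 1))
    p = expit(beta[0] + X @ np.asarray(beta[1:]))
    succ = rng.binomial(trials, p)
    return X, succ, np.full(n, trials)


class TestGlobalModel:
    def test_symmetric_data_zero_intercept(self):
        X = np.array([[1.0], [-1.0]])
        model = fit_glr(X, [30, 10], [40, 40])
        assert abs(model.coef[0]) < 1e-6

    def test_recovers_known_coefficients(self, rng):
        X, succ, trials = _simulate(rng, 1000, [-1.0, 2.0], trials=20)
        model = fit_glr(X, succ, trials)
        # 20000 cell-years: estimates well within 3 SE of truth
        se = 3.0 / np.sqrt(20000 / 4)
        assert model.coef[0] == pytest.approx(-1.0, abs=3 * se)
        assert model.coef[1] == pytest.approx(2.0, abs=3 * se)

    def test_bernoulli_case_matches_statsmodels(self, rng):
        """Independent IRLS oracle: statsmodels GLM Binomial."""
        X, succ, trials = _simulate(rng, 400, [-0.5, 1.2, -0.8], trials=1)
        model = fit_glr(X, succ, trials)
        sm_fit = sm.GLM(succ, sm.add_constant(X), family=sm.families.Binomial()).fit()
        assert np.allclose(model.coef, sm_fit.params, atol=1e-6)
        assert model.deviance == pytest.approx(sm_fit.deviance, abs=1e-6)
        assert model.log_likelihood == pytest.approx(sm_fit.llf, abs=1e-6)

    def test_binomial_case_matches_statsmodels(self, rng):
        X, succ, trials = _simulate(rng, 200, [-1.0, 1.5], trials=20)
        model = fit_glr(X, succ, trials)
        endog = np.column_stack([succ, trials - succ])
        sm_fit = sm.GLM(endog, sm.add_constant(X), family=sm.families.Binomial()).fit()
        assert np.allclose(model.coef, sm_fit.params, atol=1e-6)

    def test_no_variation_rejected(self):
        with pytest.raises(ValueError, match="variation"):
            fit_glr(np.zeros((5, 1)), np.zeros(5), np.ones(5))

    def test_complete_separation_flagged_not_crashed(self):
        X = np.linspace(-2, 2, 20).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(float)
        model = fit_glr(X, y, np.ones(20))
        assert not model.converged


class TestGeographicallyWeighted:
    def _spatial_data(self, rng, n_side=8, trials=20, amplitude=2.0):
        grid = synthetic.gen_grid(n_side, n_side, seed=5)
        coords = grid.cells[["lon", "lat"]].to_numpy()
        lat = coords[:, 1]
        beta1 = amplitude * (lat.mean() - lat) / (np.ptp(lat) / 2)  # south +, north -
        X = rng.uniform(0, 1, (len(lat), 1))
        p = expit(-0.5 + beta1 * X[:, 0])
        succ = rng.binomial(trials, p)
        return X, succ, np.full(len(lat), trials), coords, beta1

    def test_uniform_weights_reproduce_global_fit(self, rng):
        X, succ, trials, coords, _ = self._spatial_data(rng)
        glr = fit_glr(X, succ, trials)
        gwlr = fit_gwlr(X, succ, trials, coords, None)
        assert np.allclose(gwlr.coef - glr.coef[None, :], 0.0, atol=1e-6)

    def test_cell_order_permutation_invariance(self, rng):
        X, succ, trials, coords, _ = self._spatial_data(rng, n_side=6)
        m1 = fit_gwlr(X, succ, trials, coords, 12)
        perm = rng.permutation(len(succ))
        m2 = fit_gwlr(X[perm], succ[perm], trials[perm], coords[perm], 12)
        assert np.allclose(m2.coef, m1.coef[perm], atol=1e-8)
        assert m2.aicc == pytest.approx(m1.aicc, abs=1e-8)

    def test_local_coefficient_sign_recovery(self, rng):
        X, succ, trials, coords, beta1 = self._spatial_data(
            rng, n_side=10, trials=25, amplitude=3.0)
        model = fit_gwlr(X, succ, trials, coords, 30)
        est = model.coef[:, 1]
        agree = np.mean(np.sign(est) == np.sign(beta1))
        assert agree >= 0.8
        assert np.corrcoef(est, beta1)[0, 1] >= 0.7

    def test_heterogeneous_data_likelihood_beats_global(self, rng):
        X, succ, trials, coords, _ = self._spatial_data(rng, amplitude=3.0)
        glr = fit_glr(X, succ, trials)
        gwlr = fit_gwlr(X, succ, trials, coords, 20)
        assert gwlr.log_likelihood >= glr.log_likelihood
        assert aicc(gwlr.log_likelihood, gwlr.k_effective, gwlr.m) == (gwlr.aic, gwlr.aicc)

    def test_bandwidth_below_minimum_rejected(self, rng):
        X, succ, trials, coords, _ = self._spatial_data(rng, n_side=4)
        with pytest.raises(ValueError, match="bandwidth"):
            fit_gwlr(X, succ, trials, coords, 2)


class TestBandwidthSelection:
    def test_minimizer_property_and_determinism(self, rng):
        grid = synthetic.gen_grid(7, 7, seed=2)
        coords = grid.cells[["lon", "lat"]].to_numpy()
        lat = coords[:, 1]
        beta1 = 2.5 * (lat.mean() - lat) / (np.ptp(lat) / 2)
        X = rng.uniform(0, 1, (49, 1))
        succ = rng.binomial(20, expit(-0.5 + beta1 * X[:, 0]))
        trials = np.full(49, 20.0)
        bw, trace = select_bandwidth(X, succ, trials, coords, lo=5, hi=49)
        scores = dict(trace)
        assert scores[bw] <= scores[5] and scores[bw] <= scores[49]
        bw2, _ = select_bandwidth(X, succ, trials, coords, lo=5, hi=49)
        assert bw2 == bw

    def test_homogeneous_data_prefers_global_bandwidth(self, rng):
        grid = synthetic.gen_grid(6, 6, seed=9)
        coords = grid.cells[["lon", "lat"]].to_numpy()
        X = rng.uniform(0, 1, (36, 1))
        succ = rng.binomial(30, expit(-0.5 + 1.5 * X[:, 0]))
        bw, _ = select_bandwidth(X, succ, np.full(36, 30.0), coords,
                                 lo=6, hi=36, method="grid")
        assert bw >= 30  # near the upper bound: no spatial structure to exploit

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValueError, match="range"):
            select_bandwidth(np.zeros((5, 1)), np.ones(5), np.full(5, 2.0),
                             np.zeros((5, 2)), lo=10, hi=5)


class TestPredict:
    def test_sigmoid_at_zero_and_logit_roundtrip(self, rng):
        X, succ, trials = _simulate(rng, 100, [0.3, 0.7])
        model = fit_glr(X, succ, trials)
        p = predict(model, X)
        assert np.all((p > 0) & (p < 1))
        eta = X @ model.coef[1:] + model.coef[0]
        assert np.allclose(np.log(p / (1 - p)), eta, atol=1e-12)
        assert predict(model, np.array([[-model.coef[0] / model.coef[1]]]))[0] == pytest.approx(0.5)

    def test_gwlr_prediction_consistent_with_stored_local_fits(self, rng):
        grid = synthetic.gen_grid(5, 5, seed=3)
        coords = grid.cells[["lon", "lat"]].to_numpy()
        X = rng.uniform(0, 1, (25, 1))
        succ = rng.binomial(15, expit(-0.3 + 1.0 * X[:, 0]))
        model = fit_gwlr(X, succ, np.full(25, 15.0), coords, 10)
        own = model.predict(X)
        via_coords = model.predict(X, coords=coords)
        assert np.allclose(own, via_coords, atol=1e-10)

    def test_new_location_refits_locally(self, rng):
        grid = synthetic.gen_grid(5, 5, seed=3)
        coords = grid.cells[["lon", "lat"]].to_numpy()
        X = rng.uniform(0, 1, (25, 1))
        succ = rng.binomial(15, expit(-0.3 + 1.0 * X[:, 0]))
        model = fit_gwlr(X, succ, np.full(25, 15.0), coords, 12)
        new_coord = coords[:1] + 0.1
        p = model.predict(X[:1], coords=new_coord)
        assert 0.0 < p[0] < 1.0
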