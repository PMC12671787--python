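"""Terrain metrics, normalization, collinearity diagnosis, PCA reuse."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from droughtfire.covariates import (
    MinMaxNormalizer,
    PcaModel,
    minmax_fit_apply,
    network_density,
    surface_roughness,
    vif,
)


class TestTerrainMetrics:
    @pytest.mark.parametrize("elev, expected", [
        ([500.0, 500.0, 500.0], 0.0),
        ([100.0, 250.0, 175.0], 150.0),
        ([42.0], 0.0),
    ])
    def test_roughness(self, elev, expected):
        assert surface_roughness(np.array(elev)) == expected

    def test_roughness_empty_rejected(self):
        with pytest.raises(ValueError):
            surface_roughness(np.array([]))

    @pytest.mark.parametrize("L, F, expected", [(0.0, 5.0, 0.0), (10.0, 4.0, 2.5), (7.0, 7.0, 1.0)])
    def test_network_density(self, L, F, expected):
        assert network_density(L, F) == expected

    def test_network_density_bad_area(self):
        with pytest.raises(ValueError):
            network_density(1.0, 0.0)


class TestMinMax:
    def test_endpoints_midpoint_and_clipping(self):
        x = np.array([2.0, 4.0, 6.0])
        normed, params = minmax_fit_apply(x)
        assert np.allclose(normed, [0.0, 0.5, 1.0])
        future, _ = minmax_fit_apply(np.array([16.0, -3.0]), params)
        assert np.allclose(future, [1.0, 0.0])  # clipped to the trained domain

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=40)
           .filter(lambda v: max(v) > min(v)))
    def test_property_bounded_and_order_preserving(self, values):
        x = np.array(values)
        normed, _ = minmax_fit_apply(x)
        assert normed.min() == 0.0 and normed.max() == 1.0
        order = np.argsort(x, kind="stable")
        assert np.all(np.diff(normed[order]) >= 0)

    def test_constant_variable_rejected_by_name(self):
        table = pd.DataFrame({"slope": [1.0, 1.0, 1.0], "elev": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="slope"):
            MinMaxNormalizer().fit(table)

    def test_order_preserving_affine_and_roundtrip_json(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=50), "b": rng.gamma(2, 2, 50)})
        norm = MinMaxNormalizer().fit(table)
        out = norm.transform(table)
        assert ((out >= 0) & (out <= 1)).all().all()
        for c in table.columns:
            order = np.argsort(table[c].to_numpy())
            assert np.all(np.diff(out[c].to_numpy()[order]) >= 0)
        norm2 = MinMaxNormalizer.from_json(norm.to_json())
        assert norm2.transform(table).equals(out)


class TestVif:
    def test_orthogonal_columns_give_unit_vif(self):
        # +-1 design columns: zero-mean and mutually orthogonal, so R^2_j = 0
        X = pd.DataFrame({"a": [1, 1, 1, 1, -1, -1, -1, -1],
                          "b": [1, 1, -1, -1, 1, 1, -1, -1],
                          "c": [1, -1, 1, -1, 1, -1, 1, -1]}, dtype=float)
        assert np.allclose(vif(X).to_numpy(), 1.0, atol=1e-10)

    def test_duplicated_column_flagged_unbounded(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
        v = vif(X)
        assert np.isinf(v["a"]) and np.isinf(v["b"])
        assert np.isfinite(v["c"])

    def test_matches_explicit_least_squares(self, rng):
        """Oracle: 1/(1-R^2) via an explicit lstsq regression per column."""
        cov = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]])
        X = rng.multivariate_normal(np.zeros(3), cov, size=50)
        df = pd.DataFrame(X, columns=list("abc"))
        v = vif(df)
        for j, c in enumerate("abc"):
            others = np.column_stack([np.ones(50), np.delete(X, j, axis=1)])
            beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            resid = X[:, j] - others @ beta
            r2 = 1 - resid.var() / X[:, j].var()
            assert v[c] == pytest.approx(1.0 / (1.0 - r2), rel=1e-6)


class TestPca:
    def _chars(self, rng, n=120):
        base = rng.normal(size=n)
        return pd.DataFrame({
            "mdn": 0.4 * base + rng.normal(0, 0.6, n),
            "mdd": 4 + 2 * base + rng.normal(0, 0.3, n),
            "mds": -3 - 2.1 * base + rng.normal(0, 0.3, n),  # ~ -mdd
            "mdi": -0.8 - 0.2 * base + rng.normal(0, 0.4, n),
        })

    def test_rank_one_two_variable_case(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        model = PcaModel.fit(df, cumulative_target=90.0)
        assert model.variance_proportion[0] == pytest.approx(100.0, abs=1e-9)
        assert model.n_retained == 1

    def test_loadings_orthonormal_and_proportions_sum(self, rng):
        model = PcaModel.fit(self._chars(rng))
        L = model.loadings
        assert np.allclose(L.T @ L, np.eye(4), atol=1e-10)
        assert model.variance_proportion.sum() == pytest.approx(100.0)
        assert np.all(np.diff(model.variance_proportion) <= 1e-9)
        assert np.cumsum(model.variance_proportion)[model.n_retained - 1] >= 90.0

    def test_sign_convention_largest_entry_positive(self, rng):
        model = PcaModel.fit(self._chars(rng))
        for j in range(4):
            col = model.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_training_roundtrip_and_mean_centering(self, rng):
        df = self._chars(rng)
        model = PcaModel.fit(df)
        s1 = model.transform(df)
        s2 = model.transform(df)
        assert s1.equals(s2)
        means = pd.DataFrame([model.means], columns=model.variables)
        assert np.allclose(model.transform(means).to_numpy(), 0.0, atol=1e-12)

    def test_full_rank_reconstruction(self, rng):
        df = self._chars(rng)
        model = PcaModel.fit(df)
        scores = model.transform(df, n_components=4).to_numpy()
        Z = (df.to_numpy() - model.means) / model.sds
        assert np.allclose(model.inverse_transform_standardized(scores), Z, atol=1e-10)

    def test_variable_mismatch_rejected(self, rng):
        model = PcaModel.fit(self._chars(rng))
        with pytest.raises(ValueError, match="mismatch"):
            model.transform(pd.DataFrame({"mdn": [0.1], "mdd": [3.0], "mds": [-2.0]}))

    def test_json_roundtrip_is_exact(self, rng):
        df = self._chars(rng)
        model = PcaModel.fit(df)
        model2 = PcaModel.from_json(model.to_json())
        assert model2.transform(df).equals(model.transform(df))

    def test_constant_variable_rejected(self):
        df = pd.DataFrame({"mdn": [1.0] * 6, "mdd": np.arange(6.0),
                           "mds": -np.arange(6.0), "mdi": np.linspace(-1, 0, 6)})
        with pytest.raises(ValueError, match="constant"):
            PcaModel.fit(df)


class TestCollinearityPipeline:
    def test_pca_resolves_drought_characteristic_collinearity(self, rng):
        """MDD/MDS correlated at <= -0.95 inflate VIF past 10; replacing the
        four characteristics by the retained PCs brings every VIF under 10."""
        n = 200
        base = rng.normal(size=n)
        chars = pd.DataFrame({
            "mdn": 0.4 * base + rng.normal(0, 0.7, n),
            "mdd": 5 + 3 * base + rng.normal(0, 0.25, n),
            "mds": -4 - 3 * base - rng.normal(0, 0.25, n) * 0.5,
            "mdi": -0.9 - 0.3 * base + rng.normal(0, 0.3, n),
        })
        assert chars[["mdd", "mds"]].corr().iloc[0, 1] <= -0.95
        static = pd.DataFrame({"slope": rng.normal(size=n), "elev": rng.normal(size=n)})
        v = vif(pd.concat([chars, static], axis=1))
        assert v["mdd"] >= 10 and v["mds"] >= 10
        model = PcaModel.fit(chars)
        scores = model.transform(chars)
        assert np.cumsum(model.variance_proportion)[model.n_retained - 1] >= 90.0
        v2 = vif(pd.concat([scores, static], axis=1))
        assert (v2 < 10).all()
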