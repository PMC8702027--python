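"""Tests for Mantel association, BH adjustment and ordinary kriging."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

import sedscreen as ss
from sedscreen.errors import (ConfigurationError, InsufficientDataError,
                              ZeroVarianceError)
from sedscreen.spatial import (Variogram, bh_adjust, empirical_semivariogram,
                               fit_spherical)


def sites_frame(coords):
    return pd.DataFrame([{"sample_id": f"s{i}", "lon": x, "lat": y}
                         for i, (x, y) in enumerate(coords)])


class TestDistances:
    def test_one_degree_latitude(self):
        d = ss.haversine_km(0.0, 0.0, 0.0, 1.0)
        assert d == pytest.approx(111.19, abs=0.05)

    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(0)
        sites = sites_frame(zip(rng.uniform(-95.3, -94.8, 6),
                                rng.uniform(29.3, 29.8, 6)))
        m = ss.geo_distances(sites).values
        assert np.allclose(np.diag(m), 0)
        assert np.allclose(m, m.T)

    def test_squared_diff_values(self):
        d = ss.feature_distances(np.array([0.0, 1.0, 3.0]))
        assert d.values[0, 1] == 1.0
        assert d.values[0, 2] == 9.0
        assert d.values[1, 2] == 4.0

    def test_one_minus_spearman_bounds(self):
        m = pd.DataFrame([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]],
                         index=["a", "b", "c"], dtype=float)
        d = ss.feature_distances(m, mode="one_minus_spearman")
        assert d.loc["a", "b"] == pytest.approx(0.0)
        assert d.loc["a", "c"] == pytest.approx(2.0)


class TestMantel:
    def geo(self, n=7, seed=2):
        rng = np.random.default_rng(seed)
        sites = sites_frame(zip(rng.uniform(-95.3, -94.8, n),
                                rng.uniform(29.3, 29.8, n)))
        return ss.geo_distances(sites)

    def test_perfect_association(self):
        d_geo = self.geo()
        r = ss.mantel_test(d_geo, d_geo.copy(), n_perm=99, seed=0)
        assert r.statistic == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0 / 100.0)

    def test_exhaustive_matches_full_enumeration(self):
        """At n = 4, the exhaustive p equals an independently coded
        enumeration over all 24 relabelings."""
        d_geo = self.geo(n=4, seed=5)
        rng = np.random.default_rng(1)
        d_feat = ss.feature_distances(rng.normal(size=4),
                                      ids=d_geo.index)
        res = ss.mantel_test(d_geo, d_feat, exhaustive=True)
        iu = np.triu_indices(4, 1)
        x = d_geo.values[iu]
        obs = pearsonr(x, d_feat.values[iu]).statistic
        stats = []
        for perm in itertools.permutations(range(4)):
            fp = d_feat.values[np.ix_(perm, perm)]
            stats.append(pearsonr(x, fp[iu]).statistic)
        p_exact = np.mean(np.asarray(stats) >= obs - 1e-12)
        assert res.n_perm == 24
        assert res.p_value == pytest.approx(p_exact)

    def test_statistic_matches_skbio(self):
        """Cross-check the statistic against the independent scikit-bio
        implementation."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        d_geo = self.geo(n=8, seed=7)
        rng = np.random.default_rng(3)
        d_feat = ss.feature_distances(rng.normal(size=8), ids=d_geo.index)
        ours = ss.mantel_test(d_geo, d_feat, n_perm=99, seed=0)
        theirs, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d_geo.values),
            skbio_distance.DistanceMatrix(d_feat.values),
            method="pearson", permutations=0)
        assert ours.statistic == pytest.approx(float(theirs), abs=1e-12)

    @pytest.mark.parametrize("scale,offset", [(2.0, 0.0), (0.5, 3.0)])
    def test_invariant_to_linear_rescaling_of_geo(self, scale, offset):
        d_geo = self.geo()
        rng = np.random.default_rng(11)
        d_feat = ss.feature_distances(rng.normal(size=7), ids=d_geo.index)
        r1 = ss.mantel_test(d_geo, d_feat, n_perm=49, seed=5)
        d2 = d_geo * scale + offset
        d2.values[np.diag_indices(7)] = 0.0
        r2 = ss.mantel_test(d2, d_feat, n_perm=49, seed=5)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-9)
        assert r1.p_value == r2.p_value

    def test_zero_variance_rejected(self):
        d_geo = self.geo()
        d_flat = ss.feature_distances(np.zeros(7), ids=d_geo.index)
        with pytest.raises(ZeroVarianceError):
            ss.mantel_test(d_geo, d_flat, n_perm=9)

    def test_small_n_rejected(self):
        d_geo = self.geo(n=3, seed=1)
        with pytest.raises(InsufficientDataError):
            ss.mantel_test(d_geo, d_geo.copy(), n_perm=9)


class TestBH:
    def test_hand_computed_values(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_step_up_rule_on_mixed_input(self):
        p = np.array([0.005, 0.2, 0.04, 0.9])
        # hand-applied: sorted p * n/rank, then cumulative min from the top
        expected = {0.005: 0.02, 0.04: 0.08, 0.2: 0.26666666666666666, 0.9: 0.9}
        adj = bh_adjust(p)
        for pi, ai in zip(p, adj):
            assert ai == pytest.approx(expected[pi])

    def test_monotone_in_rank_order(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.001, 1.0, 50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-12)


class TestVariogram:
    def test_model_shape(self):
        v = Variogram(nugget=0.1, sill=1.0, range_km=10.0)
        assert v.gamma(0.0) == 0.0
        assert v.gamma(10.0) == pytest.approx(1.0)
        assert v.gamma(50.0) == pytest.approx(1.0)
        assert v.covariance(0.0) == pytest.approx(1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            Variogram(nugget=0.5, sill=0.2, range_km=1.0)
        with pytest.raises(ConfigurationError):
            Variogram(nugget=0.0, sill=1.0, range_km=0.0)

    def test_empirical_semivariogram_hand_example(self):
        # two points ~1.112 km apart with values 0 and 2: gamma = 2 in
        # the single occupied bin
        sites = sites_frame([(0.0, 0.0), (0.0, 0.01), (0.0, 0.02)])
        d = ss.geo_distances(sites).values
        lags, gam, cnt = empirical_semivariogram(
            d, np.array([0.0, 2.0, 4.0]), lag_size=1.5, max_lag=3.0)
        # bin 1: the two ~1.1 km pairs with increment 2; bin 2: the
        # ~2.2 km pair with increment 4
        assert cnt.tolist() == [2, 1]
        assert gam[0] == pytest.approx(0.5 * (4 + 4) / 2)
        assert gam[1] == pytest.approx(0.5 * 16)

    def test_fit_recovers_planted_spherical(self):
        v = Variogram(nugget=0.05, sill=1.2, range_km=12.0)
        lags = np.linspace(0.5, 24, 30)
        fit = fit_spherical(lags, v.gamma(lags), np.full(30, 100), 1.0)
        assert fit.nugget == pytest.approx(0.05, abs=0.02)
        assert fit.sill == pytest.approx(1.2, rel=0.05)
        assert fit.range_km == pytest.approx(12.0, rel=0.1)


class TestKriging:
    def sites(self, n=9, seed=4):
        rng = np.random.default_rng(seed)
        return sites_frame(zip(rng.uniform(-95.3, -94.9, n),
                               rng.uniform(29.3, 29.7, n)))

    def test_zero_nugget_exact_at_sites(self):
        sites = self.sites()
        rng = np.random.default_rng(1)
        values = 10.0 ** rng.uniform(1, 3, len(sites))
        v = Variogram(nugget=0.0, sill=0.8, range_km=20.0)
        targets = sites[["lon", "lat"]].values
        pred, var = ss.krige_points(sites, values, targets, v)
        assert np.allclose(pred, values, rtol=1e-8)

    def test_weights_sum_to_one(self):
        sites = self.sites()
        values = np.full(len(sites), 50.0) + np.arange(len(sites))
        v = Variogram(nugget=0.1, sill=1.0, range_km=15.0)
        rng = np.random.default_rng(2)
        targets = np.column_stack([rng.uniform(-95.3, -94.9, 40),
                                   rng.uniform(29.3, 29.7, 40)])
        _, _, w = ss.krige_points(sites, values, targets, v,
                                  return_weights=True)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-9)

    def test_constant_field_constant_prediction(self):
        sites = self.sites()
        values = np.full(len(sites), 100.0)
        v = Variogram(nugget=0.0, sill=1.0, range_km=15.0)
        targets = np.column_stack([np.linspace(-95.3, -94.9, 10),
                                   np.linspace(29.3, 29.7, 10)])
        pred, var = ss.krige_points(sites, values, targets, v)
        assert np.allclose(pred, 100.0, rtol=1e-10)
        pred_at, var_at = ss.krige_points(sites, values,
                                          sites[["lon", "lat"]].values, v)
        assert np.allclose(var_at, 0.0, atol=1e-8)

    def test_five_site_toy_matches_hand_assembled_system(self):
        """Ordinary-kriging predictions equal the direct solution of the
        OK linear system assembled independently here."""
        sites = self.sites(n=5, seed=9)
        rng = np.random.default_rng(5)
        values = rng.uniform(1.0, 3.0, 5)
        v = Variogram(nugget=0.05, sill=1.0, range_km=25.0)
        target = np.array([[-95.1, 29.5]])
        pred, _ = ss.krige_points(sites, values, target, v,
                                  log10_transform=False)
        lon, lat = sites["lon"].values, sites["lat"].values
        dmat = ss.haversine_km(lon[:, None], lat[:, None],
                               lon[None, :], lat[None, :])
        a = np.ones((6, 6))
        a[:5, :5] = v.covariance(dmat)
        a[5, 5] = 0.0
        d0 = ss.haversine_km(lon, lat, target[0, 0], target[0, 1])
        b = np.append(v.covariance(d0), 1.0)
        w = np.linalg.solve(a, b)[:5]
        assert pred[0] == pytest.approx(float(w @ values), rel=1e-10)

    def test_duplicate_sites_averaged_with_warning(self):
        sites = self.sites(n=6)
        dup = pd.concat([sites, sites.iloc[[0]]], ignore_index=True)
        dup.loc[len(dup) - 1, "sample_id"] = "dup"
        values = np.arange(len(dup), dtype=float) + 1.0
        v = Variogram(nugget=0.0, sill=1.0, range_km=15.0)
        with pytest.warns(UserWarning, match="duplicate"):
            pred, _ = ss.krige_points(dup, values, dup[["lon", "lat"]].values[:1],
                                      v, log10_transform=False)
        assert np.isfinite(pred).all()

    def test_grid_output_shape_and_bounds(self):
        sites = self.sites()
        rng = np.random.default_rng(7)
        values = 10.0 ** rng.uniform(1, 3, len(sites))
        grid, vg = ss.krige(sites, values, grid=(12, 10), lag_size_km=3.0)
        assert len(grid) == 120
        assert grid["lon"].min() < sites["lon"].min()
        assert grid["lat"].max() > sites["lat"].max()
        assert vg.sill >= vg.nugget >= 0
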