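"""Tests for the synthetic study generator."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import sedscreen as ss
from sedscreen.errors import ConfigurationError
from sedscreen.synth import (Analyte, Region, _latent_field, analytic_pod,
                             logistic_response)

from conftest import true_pods_table


def grid_pod_oracle(amplitude, log10_ec50, hill, band, step=1e-4):
    """Brute-force band-crossing search on a dense log10-dilution grid."""
    logd = np.arange(-6.0, 0.0 + step, step)
    f = logistic_response(10.0 ** logd, amplitude, log10_ec50, hill)
    exceed = np.abs(f - 1.0) > band
    if not exceed.any():
        return math.nan
    return 10.0 ** logd[np.argmax(exceed)]


class TestSites:
    def test_default_design_counts_and_regions(self, design):
        sites = ss.generate_sites(design, seed=1)
        assert len(sites) == 46
        assert set(sites["region"]) == {"HSC", "MCL", "GB"}
        assert sites["sample_id"].is_unique

    def test_determinism_byte_identical(self, design):
        a = ss.generate_sites(design, seed=3).to_csv()
        b = ss.generate_sites(design, seed=3).to_csv()
        assert a == b

    def test_zero_spread_collapses_to_center(self, design):
        regions = tuple(replace(r, spread_km=0.0) for r in design.regions)
        d0 = replace(design, regions=regions)
        sites = ss.generate_sites(d0, seed=1)
        for _, sub in sites.groupby("region"):
            dm = ss.geo_distances(sub)
            assert np.allclose(dm.values, 0.0, atol=1e-9)

    def test_invalid_region_shares_raise(self, design):
        bad = tuple(replace(r, sample_share=r.sample_share * 0.5)
                    for r in design.regions)
        with pytest.raises(ConfigurationError):
            ss.generate_sites(replace(design, regions=bad), seed=1)


class TestChemistry:
    def test_totals_are_exact_sums(self, study):
        chem = study["chemistry"]
        parents = [a.analyte_id for a in study["design"].analytes
                   if a.parent_id is None and not a.is_total]
        homologs = [a.analyte_id for a in study["design"].analytes
                    if a.parent_id is not None]
        assert np.allclose(chem["total_parent_pah16"], chem[parents].sum(axis=1),
                           rtol=0, atol=1e-9)
        assert np.allclose(chem["total_alkylated"], chem[homologs].sum(axis=1),
                           rtol=0, atol=1e-9)
        assert np.allclose(chem["total_pah"],
                           chem[parents + homologs].sum(axis=1), rtol=0, atol=1e-9)

    def test_orphan_homolog_rejected(self, design):
        bad = design.analytes + (Analyte("C1-benzo[ghi]perylene",
                                         "benzo[ghi]perylene_typo", False),)
        with pytest.raises(ConfigurationError):
            replace(design, analytes=bad).validate()

    def test_nonpositive_spatial_range_rejected(self, design):
        with pytest.raises(ConfigurationError):
            replace(design, spatial_range_km=0.0).validate()

    def test_determinism(self, design):
        sites = ss.generate_sites(design, seed=5)
        c1, _ = ss.generate_chemistry(sites, design, seed=9)
        c2, _ = ss.generate_chemistry(sites, design, seed=9)
        pd.testing.assert_frame_equal(c1, c2)

    def test_latent_field_covariance_matches_planted_model(self):
        """Empirical covariance over 200 field draws reproduces the
        analytic exponential covariance within Monte-Carlo error."""
        region = (Region("HSC", -95.2, 29.7, spread_km=10.0, sample_share=1.0),)
        d = ss.default_design(regions=region, n_samples=25,
                              spatial_range_km=20.0)
        sites = ss.generate_sites(d, seed=2)
        draws = np.array([
            _latent_field(d, sites, np.random.default_rng(1000 + k)).values
            for k in range(200)
        ])
        emp = np.cov(draws, rowvar=False)
        dist = ss.geo_distances(sites).values
        planted = d.latent_sd ** 2 * np.exp(-dist / d.spatial_range_km)
        iu = np.triu_indices(25, 1)
        assert np.corrcoef(emp[iu], planted[iu])[0, 1] > 0.8
        assert np.max(np.abs(emp - planted)) < 0.4  # ~5 SE at 200 draws

    def test_no_spatial_structure_yields_null_mantel(self, design):
        """With a vanishing autocorrelation range, single-analyte Mantel
        rejections occur at about the nominal rate."""
        d = replace(design, spatial_range_km=1e-6)
        sites = ss.generate_sites(d, seed=11)
        d_geo = ss.geo_distances(sites)
        rej = 0
        n_feat = 100
        for k in range(n_feat):
            chem, _ = ss.generate_chemistry(sites, d, seed=5000 + k)
            v = np.log10(chem["pyrene"].values)
            d_feat = ss.feature_distances(v, ids=sites["sample_id"].values)
            r = ss.mantel_test(d_geo, d_feat, n_perm=299, seed=k)
            rej += r.p_value <= 0.05
        lo, hi = 0.05 - 1.96 * math.sqrt(0.05 * 0.95 / n_feat), \
            0.05 + 1.96 * math.sqrt(0.05 * 0.95 / n_feat)
        assert lo <= rej / n_feat <= hi


class TestBioactivity:
    def test_null_endpoints_inactive_everywhere(self, study):
        design, tp = study["design"], study["truth"].true_pod
        nulls = [e.endpoint_id for e in design.endpoints if e.chem_weights is None]
        assert nulls, "design should contain null endpoints"
        assert tp[nulls].isna().all().all()

    def test_true_pod_matches_closed_form_and_grid_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            amp = rng.uniform(0.3, 0.9) * rng.choice([-1, 1])
            ec50 = rng.uniform(-3.0, -0.5)
            hill = rng.uniform(0.8, 3.0)
            band = 0.05
            pod = analytic_pod(amp, ec50, hill, band)
            oracle = grid_pod_oracle(amp, ec50, hill, band)
            if math.isnan(oracle):
                assert math.isnan(pod)
            else:
                assert abs(math.log10(pod) - math.log10(oracle)) <= 1e-4 + 1e-9
        # closed-form spot check: bottom 0.4*vehicle (amp -0.6), band 0.05
        pod = analytic_pod(-0.6, -2.0, 1.5, 0.05)
        expected = 10.0 ** (-2.0 - math.log10(0.6 / 0.05 - 1.0) / 1.5)
        assert pod == pytest.approx(expected, rel=1e-12)

    def test_doubling_chem_weights_increases_potency(self, design):
        sites = ss.generate_sites(design, seed=3)
        chem, truth_c = ss.generate_chemistry(sites, design, seed=3)
        _, t1 = ss.generate_bioactivity(chem, design, seed=3, latent=truth_c.latent)
        doubled = tuple(
            replace(e, chem_weights=tuple((a, 2 * w) for a, w in e.chem_weights))
            if e.chem_weights is not None else e
            for e in design.endpoints
        )
        _, t2 = ss.generate_bioactivity(chem, replace(design, endpoints=doubled),
                                        seed=3, latent=truth_c.latent)
        chem_eps = [e.endpoint_id for e in design.endpoints
                    if e.chem_weights is not None and e.chem_strength > 0]
        p1, p2 = t1.true_pod[chem_eps].values, t2.true_pod[chem_eps].values
        both = np.isfinite(p1) & np.isfinite(p2)
        assert both.any()
        assert np.all(p2[both] < p1[both])
        # previously active pairs may only stay active or (never) censor upward
        assert not np.any(np.isfinite(p1) & ~np.isfinite(p2))

    def test_generate_study_deterministic(self, design):
        s1 = ss.generate_study(design, seed=21)
        s2 = ss.generate_study(design, seed=21)
        pd.testing.assert_frame_equal(s1["plates"], s2["plates"])
        pd.testing.assert_frame_equal(s1["truth"].true_pod, s2["truth"].true_pod)

    def test_vehicle_wells_present_per_endpoint(self, study):
        plates, design = study["plates"], study["design"]
        veh = plates[plates["sample_id"] == "VEHICLE"]
        counts = veh.groupby("endpoint_id").size()
        assert (counts == design.vehicle_wells).all()
        assert len(counts) == len(design.endpoints)


def test_latent_contamination_recoverable_through_toxpi(design):
    """Planted-signal recoverability: across 100 simulated studies the
    rank correlation between the latent field and the overall ToxPi
    score is positive in >= 95% and above 0.5 in >= 90%."""
    from scipy.stats import spearmanr

    pos = strong = 0
    n_sim = 100
    for s in range(n_sim):
        sim = ss.generate_study(design, seed=40_000 + s)
        pods = true_pods_table(sim["truth"], design)
        tox = ss.toxpi_from_pods(pods)
        rho = spearmanr(sim["truth"].latent.loc[tox.index], tox["overall"]).statistic
        pos += rho > 0
        strong += rho > 0.5
    assert pos >= 0.95 * n_sim
    assert strong >= 0.90 * n_sim
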