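"""Radius interpolation, flux arithmetic, and E1/E2 error propagation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tidalcarbon.errors import ConfigurationError, ValidationError
from tidalcarbon.geo import haversine_km
from tidalcarbon.upscale import (
    aggregate,
    neighbors_within,
    polygon_flux,
    regional_site_stats,
    underestimation_pct,
    upscale_inventory,
    upscale_stratified,
    upscale_uniform,
)
from conftest import make_sites_frame


def make_polygons(coords, areas=1.0, region="Mid Atlantic"):
    n = len(coords)
    areas = np.broadcast_to(areas, n).astype(float)
    return pd.DataFrame(
        {
            "polygon_id": [f"p{i}" for i in range(n)],
            "lat": [c[0] for c in coords],
            "lon": [c[1] for c in coords],
            "area_km2": areas,
            "vegetation": "salt_marsh",
            "region": region,
            "state": "MD",
        }
    )


class TestNeighborsWithin:
    def test_site_at_centroid_included(self):
        sites = make_sites_frame([38.0], [-75.0], [100.0])
        assert len(neighbors_within(38.0, -75.0, sites, 100.0)) == 1

    def test_boundary_distance_inclusive(self):
        site_lat, site_lon = 38.9, -75.0
        radius = haversine_km(38.0, -75.0, site_lat, site_lon)
        sites = make_sites_frame([site_lat], [site_lon], [100.0])
        assert len(neighbors_within(38.0, -75.0, sites, radius)) == 1
        assert len(neighbors_within(38.0, -75.0, sites, radius * 0.999)) == 0

    def test_matches_exhaustive_scan(self, rng):
        sites = make_sites_frame(
            rng.uniform(25, 45, 80), rng.uniform(-120, -70, 80), rng.uniform(50, 300, 80)
        )
        for _ in range(20):
            lat, lon = float(rng.uniform(25, 45)), float(rng.uniform(-120, -70))
            got = set(neighbors_within(lat, lon, sites, 150.0)["site_id"])
            expected = {
                row.site_id
                for row in sites.itertuples()
                if haversine_km(lat, lon, row.lat, row.lon) <= 150.0
            }
            assert got == expected


REGIONAL = pd.DataFrame({"region": ["Mid Atlantic"], "car_mean": [176.5], "car_se": [14.0]})


class TestInterpolateCar:
    def test_identical_neighbors_zero_se(self):
        sites = make_sites_frame([38.0, 38.1, 38.2], [-75.0] * 3, [200.0] * 3)
        est = upscale_inventory(make_polygons([(38.1, -75.0)]), sites, REGIONAL)
        row = est.iloc[0]
        assert row["car_mean"] == pytest.approx(200.0)
        assert row["car_se"] == 0.0
        assert row["method"] == "interpolated"
        assert row["n_neighbors"] == 3

    def test_single_neighbor_falls_back_to_region(self):
        sites = make_sites_frame([38.0], [-75.0], [999.0])
        est = upscale_inventory(make_polygons([(38.0, -75.0)]), sites, REGIONAL)
        row = est.iloc[0]
        assert row["method"] == "regional_fallback"
        assert row["car_mean"] == pytest.approx(176.5)
        assert row["car_se"] == pytest.approx(14.0)
        assert row["ci95"] == pytest.approx(1.96 * 14.0)

    def test_two_neighbors_interpolate(self):
        sites = make_sites_frame([38.0, 38.1], [-75.0] * 2, [100.0, 300.0])
        est = upscale_inventory(make_polygons([(38.05, -75.0)]), sites, REGIONAL)
        assert est.iloc[0]["method"] == "interpolated"
        assert est.iloc[0]["car_mean"] == pytest.approx(200.0)

    def test_sample_se_of_three_neighbors(self):
        sites = make_sites_frame([38.0, 38.1, 38.2], [-75.0] * 3, [100.0, 200.0, 300.0])
        est = upscale_inventory(make_polygons([(38.1, -75.0)]), sites, REGIONAL)
        # SD({100,200,300}) = 100, SE = 100/sqrt(3) = 57.735
        assert est.iloc[0]["car_se"] == pytest.approx(100.0 / np.sqrt(3), abs=1e-9)

    def test_missing_region_is_configuration_error(self):
        sites = make_sites_frame([38.0], [-75.0], [100.0])
        polygons = make_polygons([(38.0, -75.0)], region="Atlantis")
        with pytest.raises(ConfigurationError, match="Atlantis"):
            upscale_inventory(polygons, sites, REGIONAL)

    def test_zero_radius_rejected(self):
        sites = make_sites_frame([38.0], [-75.0], [100.0])
        with pytest.raises(ValidationError):
            upscale_inventory(make_polygons([(38.0, -75.0)]), sites, REGIONAL, radius_km=0.0)


class TestFluxArithmetic:
    def test_unit_bridge(self):
        flux, se = polygon_flux(100.0, 0.0, 1.0)
        assert flux == pytest.approx(1e-4, abs=1e-18)
        assert se == 0.0

    def test_national_mean_over_inventory_area(self):
        assert polygon_flux(161.8, 0.0, 25892.0)[0] == pytest.approx(4.189, abs=1e-3)

    def test_low_assumption_baseline(self):
        assert polygon_flux(60.0, 0.0, 24945.9)[0] == pytest.approx(1.497, abs=1e-3)


class TestAggregate:
    def _estimates(self, fluxes, ses, region="Mid Atlantic"):
        n = len(fluxes)
        return pd.DataFrame(
            {
                "polygon_id": [f"p{i}" for i in range(n)],
                "region": region,
                "state": "MD",
                "vegetation": "salt_marsh",
                "flux_Tg_yr": fluxes,
                "flux_se_Tg_yr": ses,
            }
        )

    def test_quadrature_scaling(self):
        out = aggregate(self._estimates([1.0] * 4, [1.0] * 4))
        assert out.iloc[0]["flux_se_Tg_yr"] == pytest.approx(2.0)
        assert out.iloc[0]["ci95_Tg_yr"] == pytest.approx(3.92)

    def test_single_polygon_passthrough(self):
        out = aggregate(self._estimates([0.5], [0.2]))
        assert out.iloc[0]["total_flux_Tg_yr"] == pytest.approx(0.5)
        assert out.iloc[0]["flux_se_Tg_yr"] == pytest.approx(0.2)

    def test_regional_sum_reproduces_national_total(self):
        fluxes = [0.710, 0.078, 1.176, 2.562, 0.372, 0.027, 0.041]
        out = aggregate(self._estimates(fluxes, [0.0] * 7))
        assert out.iloc[0]["total_flux_Tg_yr"] == pytest.approx(4.966, abs=1e-12)

    def test_permutation_invariance_and_partition_additivity(self, rng):
        fluxes = rng.uniform(0, 1, 30)
        ses = rng.uniform(0, 0.1, 30)
        regions = rng.choice(["A", "B", "C"], 30)
        est = self._estimates(fluxes, ses, region=regions)
        shuffled = est.sample(frac=1.0, random_state=1).reset_index(drop=True)
        nat, nat_shuf = aggregate(est), aggregate(shuffled)
        assert nat.iloc[0]["total_flux_Tg_yr"] == pytest.approx(nat_shuf.iloc[0]["total_flux_Tg_yr"])
        by_region = aggregate(est, by="region")
        assert by_region["total_flux_Tg_yr"].sum() == pytest.approx(nat.iloc[0]["total_flux_Tg_yr"])
        # variances (not SEs) add across a disjoint partition
        assert (by_region["flux_se_Tg_yr"] ** 2).sum() == pytest.approx(
            nat.iloc[0]["flux_se_Tg_yr"] ** 2
        )

    def test_empty_input_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            out = aggregate(self._estimates([], []))
        assert out.iloc[0]["total_flux_Tg_yr"] == 0.0

    def test_error_propagation_matches_monte_carlo(self, rng):
        """E1 quadrature equals the empirical SD of independently drawn sums."""
        n_poly = 40
        fluxes = rng.uniform(0.001, 0.05, n_poly)
        ses = rng.uniform(0.0005, 0.01, n_poly)
        out = aggregate(self._estimates(fluxes, ses))
        draws = rng.normal(fluxes, ses, size=(100_000, n_poly)).sum(axis=1)
        assert out.iloc[0]["flux_se_Tg_yr"] == pytest.approx(draws.std(ddof=1), rel=0.03)


class TestThreeEstimators:
    def test_uniform_national_value(self):
        assert upscale_uniform(161.8, 25892.0) == pytest.approx(4.189, abs=1e-3)

    def test_stratified_single_group_equals_uniform(self):
        assert upscale_stratified({"a": 150.0}, {"a": 1000.0}) == pytest.approx(
            upscale_uniform(150.0, 1000.0)
        )

    def test_mismatched_groups_rejected(self):
        with pytest.raises(ValidationError):
            upscale_stratified({"a": 1.0}, {"b": 1.0})

    def test_homogeneous_field_consistency(self):
        """All three estimators coincide when every site shares one CAR."""
        c = 140.0
        lats = np.linspace(37.2, 39.0, 12)
        sites = make_sites_frame(lats, [-75.0] * 12, [c] * 12)
        polygons = make_polygons([(lat, -75.0) for lat in lats[:6]], areas=np.linspace(1, 6, 6))
        total_area = float(polygons["area_km2"].sum())
        uniform = upscale_uniform(c, total_area)
        stratified = upscale_stratified({"Mid Atlantic": c}, {"Mid Atlantic": total_area})
        interpolated = aggregate(
            upscale_inventory(polygons, sites, regional_site_stats(sites))
        ).iloc[0]["total_flux_Tg_yr"]
        assert uniform == pytest.approx(c * total_area * 1e-6, rel=1e-12)
        assert stratified == pytest.approx(uniform, rel=1e-12)
        assert interpolated == pytest.approx(uniform, rel=1e-12)

    def test_all_fallback_equals_stratified_regional(self):
        """With every polygon on regional fallback, interpolation reduces to
        the stratified regional estimator exactly."""
        sites = make_sites_frame([44.0, 44.1, 44.2], [-68.0] * 3, [150.0, 160.0, 170.0], regions=["New England"] * 3)
        # polygons far from every site
        polygons = make_polygons([(30.0, -85.0), (30.5, -85.5)], areas=[100.0, 200.0], region="New England")
        stats = regional_site_stats(sites)
        est = upscale_inventory(polygons, sites, stats)
        assert (est["method"] == "regional_fallback").all()
        total = aggregate(est).iloc[0]["total_flux_Tg_yr"]
        expected = upscale_stratified({"New England": 160.0}, {"New England": 300.0})
        assert total == pytest.approx(expected, rel=1e-12)


class TestUnderestimation:
    def test_hotspot_versus_national_mean(self):
        assert underestimation_pct(271.9, 161.8, ndigits=0) == 40
        assert underestimation_pct(271.9, 161.8) == pytest.approx(40.49, abs=0.01)

    def test_equal_means_zero(self):
        assert underestimation_pct(150.0, 150.0) == 0.0

    def test_double_mean_is_half(self):
        assert underestimation_pct(200.0, 100.0) == pytest.approx(50.0)

    def test_nonpositive_group_mean_rejected(self):
        with pytest.raises(ValidationError):
            underestimation_pct(0.0, 100.0)
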