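import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm

from isomigrate import WorldConfig, make_calibration_sites, make_migrants, make_world
from isomigrate.synthetic import (
    SEASON_WINDOW,
    PhenologyModel,
    PrecipModel,
    TissueModel,
)


def ols_slope(x, y):
    """Oracle: simple-regression slope and its standard error."""
    fit = sm.OLS(y, sm.add_constant(np.asarray(x))).fit()
    return fit.params[1], fit.bse[1]


class TestMakeWorld:
    def test_same_seed_identical_grids(self, small_world_config):
        a = make_world(small_world_config)
        b = make_world(small_world_config)
        np.testing.assert_array_equal(a.precip_truth.values,
                                      b.precip_truth.values)
        np.testing.assert_array_equal(a.elevation.values, b.elevation.values)

    def test_different_seed_differs(self, small_world_config):
        other = dataclasses.replace(small_world_config, rng_seed=43)
        a = make_world(small_world_config)
        b = make_world(other)
        assert not np.array_equal(a.precip_truth.values,
                                  b.precip_truth.values)

    def test_noiseless_latitude_only_is_affine(self, noiseless_config):
        world = make_world(noiseless_config)
        _, lats = world.precip_truth.cell_centers()
        np.testing.assert_allclose(world.precip_truth.values,
                                   -10.0 - 1.5 * lats, rtol=1e-12)

    def test_coefficient_recovery_by_ols_oracle(self, small_world):
        w = small_world
        X = sm.add_constant(np.column_stack(
            [g.values.ravel() for g in w.covariates]))
        fit = sm.OLS(w.precip_truth.values.ravel(), X).fit()
        pm = w.config.precip_model
        truth = [pm.temp_slope, pm.elev_slope, pm.lat_slope, pm.lon_slope]
        for est, se, true in zip(fit.params[1:], fit.bse[1:], truth):
            assert abs(est - true) < 2 * se

    def test_grid_dimensions_match_config(self, small_world):
        assert small_world.precip_truth.shape == (30, 20)
        assert small_world.mask.grid.shape == (30, 20)

    def test_degenerate_ranges_rejected(self):
        with pytest.raises(ValueError, match="latitude"):
            WorldConfig(lat_range=(40.0, 40.0))
        with pytest.raises(ValueError, match="resolution"):
            WorldConfig(resolution=0.0)


class TestCalibrationSites:
    def test_default_design_totals(self, small_world):
        sites = make_calibration_sites(small_world)
        assert len(sites) == 10
        assert sum(s.n_birds for s in sites) == 186

    def test_single_bird_site_reports_zero_sd(self, small_world):
        sites = make_calibration_sites(small_world, n_sites=5,
                                       birds_per_site=1)
        assert all(s.feather_sd == 0.0 for s in sites)
        assert all(s.n_birds == 1 for s in sites)

    def test_noiseless_identity_tissue_model(self, noiseless_config):
        world = make_world(noiseless_config)
        sites = make_calibration_sites(world, n_sites=6, birds_per_site=10)
        for s in sites:
            assert s.feather_mean == pytest.approx(s.env_d2h, abs=1e-9)

    def test_pooled_regression_recovers_tissue_model(self, small_world_config):
        config = dataclasses.replace(
            small_world_config,
            tissue_model=TissueModel(intercept=-12.0, slope=1.3, site_sd=2.0),
        )
        world = make_world(config)
        sites = make_calibration_sites(world, n_sites=10, birds_per_site=19)
        env = [s.env_d2h for s in sites]
        fm = [s.feather_mean for s in sites]
        slope, se = ols_slope(env, fm)
        assert abs(slope - 1.3) < 2 * max(se, 1e-6)

    def test_too_many_sites_rejected(self, noiseless_config):
        world = make_world(noiseless_config)
        n_cells = world.mask.n_inside
        with pytest.raises(ValueError, match="exceeds"):
            make_calibration_sites(world, n_sites=n_cells + 1,
                                   birds_per_site=1)

    def test_sites_inside_range(self, small_world):
        sites = make_calibration_sites(small_world)
        for s in sites:
            row, col = small_world.mask.grid.index_of(s.lon, s.lat)
            assert small_world.mask.inside()[row, col]


class TestMakeMigrants:
    def test_default_cohort_design(self, small_world):
        migrants = make_migrants(small_world)
        assert len(migrants) == 150
        by_year_sex = {}
        for m in migrants:
            by_year_sex.setdefault((m.year, m.sex), 0)
            by_year_sex[(m.year, m.sex)] += 1
        assert by_year_sex == {(y, s): 25 for y in (2010, 2011, 2014)
                               for s in ("F", "M")}

    def test_arrival_window_respected(self, small_world):
        lo, hi = SEASON_WINDOW
        for m in make_migrants(small_world):
            assert lo <= m.ordinal_day <= hi
            assert m.capture_date.timetuple().tm_yday == m.ordinal_day

    def test_null_phenology_slope_uncorrelated(self, small_world_config):
        config = dataclasses.replace(
            small_world_config,
            phenology_model=PhenologyModel(intercept=260.0, slope=0.0,
                                           resid_sd=8.0),
        )
        world = make_world(config)
        corrs = []
        for seed in range(5):
            w = make_world(dataclasses.replace(config, rng_seed=seed))
            m = make_migrants(w)
            corrs.append(np.corrcoef([b.ordinal_day for b in m],
                                     [b.natal_lat for b in m])[0, 1])
        # mean correlation across replicates near zero
        assert abs(np.mean(corrs)) < 0.1

    def test_phenology_slope_recovered_by_ols(self, small_world_config):
        # pool several replicate cohorts so the sampling error of a
        # single 150-bird draw cannot dominate the check
        lats, days = [], []
        for seed in range(4):
            w = make_world(dataclasses.replace(small_world_config,
                                               rng_seed=seed))
            for m in make_migrants(w):
                lats.append(m.natal_lat)
                days.append(m.ordinal_day)
        slope, se = ols_slope(lats, days)
        assert abs(slope - 2.0) < 2 * se

    def test_masses_exceed_fat_free_mass(self, small_world):
        mm = small_world.config.morphometry_model
        for m in make_migrants(small_world):
            a, b = mm.fat_free_coeff[m.sex]
            assert m.mass_g >= a + b * m.wing_chord_mm

    def test_feather_values_follow_tissue_model(self, small_world):
        # joint recovery: regress feather values on precipitation at the
        # true natal cells; slope within 2 SE of the generating value
        w = small_world
        migrants = make_migrants(w)
        precip = []
        for m in migrants:
            row, col = w.precip_truth.index_of(m.natal_lon, m.natal_lat)
            precip.append(w.precip_truth.values[row, col])
        slope, se = ols_slope(precip, [m.feather_d2h for m in migrants])
        assert abs(slope - w.config.tissue_model.slope) < 2 * se

    def test_invalid_counts_rejected(self, small_world):
        with pytest.raises(ValueError, match="positive"):
            make_migrants(small_world, per_year={2010: 0})
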