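import numpy as np
import pytest
from scipy import stats

from isomigrate import (
    Migrant,
    RangeMask,
    assign_cohort,
    centroid_top_fraction,
    likelihood_surface,
)
from isomigrate.assignment import bird_seed

from conftest import make_grid, full_mask


def surfaces_from(mu_values, sigma_values):
    mu = make_grid(mu_values)
    sigma = mu.with_values(np.asarray(sigma_values, dtype=float))
    return mu, sigma, full_mask(mu)


class TestLikelihoodSurface:
    def test_constant_surface_is_uniform(self):
        mu, sigma, mask = surfaces_from(np.full((4, 5), -100.0),
                                        np.full((4, 5), 10.0))
        surf = likelihood_surface(-87.0, mu, sigma, mask)
        np.testing.assert_allclose(surf.probs.values, 1.0 / 20, rtol=1e-12)

    def test_mode_at_matching_cell(self):
        mu = np.linspace(-140, -60, 12).reshape(3, 4)
        mu_g, sigma, mask = surfaces_from(mu, np.full((3, 4), 3.0))
        target = mu[1, 2]
        surf = likelihood_surface(target, mu_g, sigma, mask)
        assert np.unravel_index(np.argmax(surf.probs.values),
                                (3, 4)) == (1, 2)

    def test_three_cell_brute_force_oracle(self):
        # independent evaluation of the normal density + renormalization
        mu, sigma, mask = surfaces_from([[-60.0, -100.0, -140.0]],
                                        [[10.0, 10.0, 10.0]])
        surf = likelihood_surface(-100.0, mu, sigma, mask)
        dens = stats.norm.pdf(-100.0, loc=[-60.0, -100.0, -140.0], scale=10.0)
        expected = dens / dens.sum()
        np.testing.assert_allclose(surf.probs.values[0], expected,
                                   rtol=1e-12)

    def test_masked_cells_carry_no_mass(self):
        mu, sigma, _ = surfaces_from(np.full((4, 4), -100.0),
                                     np.full((4, 4), 5.0))
        sel = np.zeros((4, 4))
        sel[:2, :] = 1.0
        mask = RangeMask(mu.with_values(sel))
        surf = likelihood_surface(-100.0, mu, sigma, mask)
        outside = surf.probs.values[~mask.inside()]
        assert np.all(outside == surf.probs.nodata_value)
        assert surf.probs.valid_values().sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_sigma_rejected(self):
        mu, sigma, mask = surfaces_from(np.full((2, 2), -100.0),
                                        np.zeros((2, 2)))
        with pytest.raises(ValueError, match="SD"):
            likelihood_surface(-90.0, mu, sigma, mask)

    def test_empty_support_rejected(self):
        mu = make_grid(np.full((2, 2), -9999.0))
        sigma = mu.with_values(np.full((2, 2), 5.0))
        mask = RangeMask(mu.with_values(np.array([[1.0, 0.0], [0.0, 0.0]])))
        with pytest.raises(ValueError, match="empty support"):
            likelihood_surface(-90.0, mu, sigma, mask)

    def test_halving_sigma_sharpens_maximum(self):
        mu = np.linspace(-140, -60, 24).reshape(4, 6)
        mu_g, sig1, mask = surfaces_from(mu, np.full((4, 6), 8.0))
        sig2 = mu_g.with_values(np.full((4, 6), 4.0))
        broad = likelihood_surface(-95.0, mu_g, sig1, mask)
        sharp = likelihood_surface(-95.0, mu_g, sig2, mask)
        assert sharp.probs.valid_values().max() > broad.probs.valid_values().max()

    def test_no_underflow_on_extreme_observation(self):
        mu, sigma, mask = surfaces_from(np.full((5, 5), -100.0),
                                        np.full((5, 5), 0.5))
        surf = likelihood_surface(-500.0, mu, sigma, mask)
        assert surf.probs.valid_values().sum() == pytest.approx(1.0, abs=1e-9)


class TestCentroid:
    def test_single_cell_support(self):
        mu, sigma, _ = surfaces_from([[-100.0, -100.0]], [[5.0, 5.0]])
        mask = RangeMask(mu.with_values(np.array([[1.0, 0.0]])))
        surf = likelihood_surface(-100.0, mu, sigma, mask)
        for seed in (0, 1, 99):
            cen = centroid_top_fraction(surf, top_fraction=1.0, seed=seed)
            assert (cen.lon, cen.lat) == mu.cell_center(0, 0)

    def test_symmetric_surface_recovers_axis(self):
        # probabilities symmetric about the central meridian of a 5-col grid
        mu = np.tile(np.array([-120.0, -100.0, -90.0, -100.0, -120.0]),
                     (5, 1))
        mu_g, sigma, mask = surfaces_from(mu, np.full((5, 5), 10.0))
        surf = likelihood_surface(-90.0, mu_g, sigma, mask)
        axis_lon = mu_g.cell_center(0, 2)[0]
        cens = [centroid_top_fraction(surf, top_fraction=1.0,
                                      n_resample=400, seed=s).lon
                for s in range(20)]
        se = np.std(cens) / np.sqrt(len(cens))
        assert abs(np.mean(cens) - axis_lon) < 4 * max(se, 1e-3)

    def test_ten_cell_closed_form_oracle(self):
        probs = np.array([[0.30, 0.25, 0.10, 0.08, 0.07,
                           0.06, 0.05, 0.04, 0.03, 0.02]])
        grid = make_grid(probs)
        from isomigrate.assignment import AssignmentSurface
        surf = AssignmentSurface(bird_id="b", probs=grid)
        # top 20% of 10 cells = 2 cells (0.30 at col 0, 0.25 at col 1)
        cen = centroid_top_fraction(surf, top_fraction=0.2,
                                    n_resample=20000, seed=0)
        lon0, lat0 = grid.cell_center(0, 0)
        lon1, _ = grid.cell_center(0, 1)
        # closed-form probability-weighted mean over the two cells
        expected = (0.30 * lon0 + 0.25 * lon1) / 0.55
        assert cen.lat == pytest.approx(lat0)
        assert cen.lon == pytest.approx(expected, abs=0.02)
        assert cen.n_cells_top == 2

    def test_top_fraction_bounds(self):
        mu, sigma, mask = surfaces_from([[-100.0, -90.0]], [[5.0, 5.0]])
        surf = likelihood_surface(-95.0, mu, sigma, mask)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="top_fraction"):
                centroid_top_fraction(surf, top_fraction=bad)

    def test_deterministic_under_seed(self):
        mu = np.linspace(-140, -60, 30).reshape(5, 6)
        mu_g, sigma, mask = surfaces_from(mu, np.full((5, 6), 6.0))
        surf = likelihood_surface(-100.0, mu_g, sigma, mask)
        a = centroid_top_fraction(surf, seed=7)
        b = centroid_top_fraction(surf, seed=7)
        assert (a.lat, a.lon) == (b.lat, b.lon)


class TestCohort:
    @staticmethod
    def _bird(bird_id, d2h):
        return Migrant(bird_id=bird_id, sex="F", year=2010, capture_date=None,
                       ordinal_day=250, mass_g=3.4, wing_chord_mm=45.0,
                       feather_d2h=d2h)

    def _world(self):
        mu = np.linspace(-150, -50, 40).reshape(5, 8)
        return surfaces_from(mu, np.full((5, 8), 5.0))

    def test_cohort_of_one_matches_single_bird_path(self):
        mu, sigma, mask = self._world()
        bird = self._bird("solo", -100.0)
        surfaces, centroids, failures = assign_cohort(
            [bird], mu, sigma, mask, seed=11)
        assert not failures
        direct = likelihood_surface(-100.0, mu, sigma, mask, bird_id="solo")
        np.testing.assert_array_equal(surfaces[0].probs.values,
                                      direct.probs.values)
        direct_cen = centroid_top_fraction(direct,
                                           seed=bird_seed(11, "solo"))
        assert centroids[0].lat == direct_cen.lat

    def test_identical_birds_identical_surfaces(self):
        mu, sigma, mask = self._world()
        twins = [self._bird("a", -95.0), self._bird("b", -95.0)]
        surfaces, centroids, _ = assign_cohort(twins, mu, sigma, mask, seed=3)
        np.testing.assert_array_equal(surfaces[0].probs.values,
                                      surfaces[1].probs.values)
        same_seed = centroid_top_fraction(surfaces[1],
                                          seed=bird_seed(3, "a"))
        assert centroids[0].lat == same_seed.lat

    def test_failures_collected_not_fatal(self):
        mu, sigma, mask = self._world()
        bad_sigma = sigma.with_values(np.zeros(sigma.shape))
        birds = [self._bird("x", -90.0)]
        _, _, failures = assign_cohort(birds, mu, bad_sigma, mask, seed=0)
        assert set(failures) == {"x"}

    def test_fills_centroid_fields_in_place(self):
        mu, sigma, mask = self._world()
        bird = self._bird("fill", -110.0)
        assign_cohort([bird], mu, sigma, mask, seed=5)
        assert bird.centroid_lat is not None
        assert bird.centroid_lon is not None

    def test_empty_cohort_rejected(self):
        mu, sigma, mask = self._world()
        with pytest.raises(ValueError, match="empty"):
            assign_cohort([], mu, sigma, mask)


class TestBirdSeed:
    def test_below_31_bits_and_stable(self):
        s1 = bird_seed(12345, "Y2010_F001")
        assert 0 <= s1 < 2 ** 31
        assert s1 == bird_seed(12345, "Y2010_F001")
        assert s1 != bird_seed(12345, "Y2010_F002")
        assert s1 != bird_seed(12346, "Y2010_F001")
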