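"""Generator correctness: GP draws, count laws, event-level REM data."""

import math

import numpy as np
import pytest
from scipy import special

from ctdensity._gp import sqexp_kernel
from ctdensity.synthetic import (
    CountSimParams,
    SurveyDesign,
    simulate_counts,
    simulate_gp_curve,
    simulate_rem_events,
)


class TestGPCurve:
    def test_zero_sd_gives_zero_vector(self):
        np.testing.assert_array_equal(simulate_gp_curve(5, 0.0, 1.0, seed=0),
                                      np.zeros(5))

    def test_long_lengthscale_limit_is_constant(self):
        x = simulate_gp_curve(10, 1.0, 1e6, seed=1)
        assert np.std(x) < 1e-3

    def test_nonpositive_lengthscale_raises(self):
        with pytest.raises(ValueError):
            simulate_gp_curve(5, 1.0, 0.0, seed=0)

    def test_empirical_covariance_matches_kernel(self):
        n, sd, ls, reps = 3, 1.3, 1.7, 10_000
        rng = np.random.default_rng(7)
        draws = np.stack(
            [simulate_gp_curve(n, sd, ls, rng) for _ in range(reps)]
        )
        emp = np.cov(draws.T)
        K = sqexp_kernel(np.arange(1.0, n + 1), sd, ls)
        # MC standard error of a covariance entry ~ sqrt(2/reps)*var scale
        mc_se = 3.0 * math.sqrt(2.0 / reps) * sd * sd
        assert np.all(np.abs(emp - K) < 3 * mc_se + 0.01)

    def test_same_seed_reproduces(self):
        a = simulate_gp_curve(6, 0.8, 2.0, seed=42)
        b = simulate_gp_curve(6, 0.8, 2.0, seed=42)
        np.testing.assert_array_equal(a, b)


class TestSimulateCounts:
    def test_zero_detection_gives_zero_counts(self):
        design = SurveyDesign(n_sites=6, n_years=3, days_per_year=4)
        params = CountSimParams(beta0=np.log([2.0]),
                                p_st=np.full((1, 3), 1e-300))
        _, table = simulate_counts(design, params, seed=0)
        assert table.counts.sum() == 0

    def test_poisson_detection_mean(self):
        # N fixed large-sample check: mean daily count = lambda-free N*p
        design = SurveyDesign(n_sites=400, n_years=1, days_per_year=250)
        params = CountSimParams(beta0=np.array([np.log(4.0)]),
                                trend_gp_sd=0.0, det_gp_sd=0.0,
                                p_st=np.array([[0.5]]))
        truth, table = simulate_counts(design, params, seed=3)
        # condition on the realized N field
        expected = truth.N.sum() * 0.5 * 250
        total = table.counts.sum()
        se = math.sqrt(expected)
        assert abs(total - expected) < 3 * se

    def test_binomial_counts_bounded_by_N(self):
        design = SurveyDesign(n_sites=30, n_years=2, days_per_year=10)
        params = CountSimParams(beta0=np.array([np.log(4.0)]),
                                p_st=np.full((1, 2), 0.5))
        truth, table = simulate_counts(design, params,
                                       detection_family="binomial", seed=4)
        assert np.all(table.counts <= truth.N[:, :, None, :])

    def test_unknown_family_raises(self):
        with pytest.raises(ValueError):
            simulate_counts(SurveyDesign(), detection_family="negbin", seed=0)

    def test_beta_detection_rates_center_on_community_mean(self):
        design = SurveyDesign(n_sites=2, n_years=4, days_per_year=2)
        draws = []
        pts = []
        for seed in range(400):
            truth, _ = simulate_counts(
                design, CountSimParams(beta0=np.log([0.5, 2.0, 7.5]), tau=5.0),
                seed=seed,
            )
            draws.append(truth.p_st - truth.p_t[None, :])
            pts.append(truth.p_t)
        diff = np.concatenate(draws).ravel()
        # E[p_st | p_t] = p_t: the average centred deviation tends to 0
        assert abs(diff.mean()) < 3 * diff.std() / math.sqrt(diff.size)

    def test_effort_mask_zeroes_counts(self):
        mask = np.ones((4, 5, 2), dtype=bool)
        mask[0, :, 0] = False
        design = SurveyDesign(n_sites=4, n_years=2, days_per_year=5, effort=mask)
        _, table = simulate_counts(
            design, CountSimParams(beta0=np.array([2.0]), p_st=np.full((1, 2), 0.9)),
            seed=5,
        )
        assert table.counts[:, 0, :, 0].sum() == 0
        assert table.counts.sum() > 0

    def test_seed_reproducibility(self):
        t1, c1 = simulate_counts(SurveyDesign(), seed=9)
        t2, c2 = simulate_counts(SurveyDesign(), seed=9)
        np.testing.assert_array_equal(c1.counts, c2.counts)
        np.testing.assert_array_equal(t1.lam, t2.lam)


class TestSimulateREM:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_rem_events(D=1.0, speed_modes=[(5.0, 1.0, 0.7)], seed=0)

    def test_requested_effective_geometry_is_solved_exactly(self):
        sim = simulate_rem_events(D=2.0, v=6.0, r=0.005, theta=0.8,
                                  sigma_angle=0.5, seed=0)
        # angle: effective angle of the solved field of view equals theta
        eff = 2 * 0.5 * math.sqrt(math.pi / 2) * special.erf(
            sim.half_fov_rad / (math.sqrt(2) * 0.5)
        )
        assert eff == pytest.approx(0.8, abs=1e-10)
        # radius: truncated EDR of the solved sigma equals r
        s = sim.sigma_radius_km
        edr = math.sqrt(2 * s * s * (1 - math.exp(-sim.r_max_km**2 / (2 * s * s))))
        assert edr == pytest.approx(0.005, abs=1e-12)

    def test_unattainable_angle_raises(self):
        with pytest.raises(ValueError, match="unattainable"):
            simulate_rem_events(D=1.0, theta=2.0, sigma_angle=0.3, seed=0)

    def test_angles_lie_in_field_of_view(self):
        sim = simulate_rem_events(D=8.0, v=6.0, r=0.005, theta=0.8,
                                  effort_cam_days=2000, seed=3)
        a = np.array([e.entry_angle_rad for e in sim.events])
        assert np.all(np.abs(a) <= sim.half_fov_rad + 1e-12)

    def test_radii_respect_truncation(self):
        sim = simulate_rem_events(D=8.0, v=6.0, r=0.005, theta=0.8,
                                  effort_cam_days=2000, seed=4)
        radii_km = np.array([e.entry_radius_m for e in sim.events]) / 1000.0
        assert np.all(radii_km <= sim.r_max_km)

    def test_behaviour_labels_track_modes(self):
        sim = simulate_rem_events(
            D=6.0, r=0.005, theta=0.8, effort_cam_days=2000,
            speed_modes=[(2.0, 0.1, 0.5), (15.0, 0.5, 0.5)], seed=5,
        )
        labels = {e.behaviour for e in sim.events}
        assert labels == {"mode0", "mode1"}
        slow = [e.speed_km_day for e in sim.events if e.behaviour == "mode0"]
        fast = [e.speed_km_day for e in sim.events if e.behaviour == "mode1"]
        assert max(slow) < min(fast)
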