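"""Random-encounter-model estimators against analytic and MC oracles."""

import math

import numpy as np
import pytest
from scipy import special

from ctdensity.rem import (
    REMParams,
    encounter_rate,
    estimate_speeds,
    fit_behavior_modes,
    fit_detection_angle,
    fit_detection_radius,
    rem_density,
    rem_se_delta,
)
from ctdensity.synthetic import simulate_rem_events
from tests.conftest import make_sequence


def _params(rate=0.1, v=5.0, r=0.005, theta=0.8, rate_se=None, v_se=None,
            r_se=None, theta_se=None):
    return REMParams(
        encounter_rate=rate, encounter_rate_se=rate_se,
        day_range=v, day_range_se=v_se,
        eff_radius_km=r, eff_radius_se=r_se,
        eff_angle_rad=theta, eff_angle_se=theta_se,
    )


class TestEncounterRate:
    def test_zero_events(self, deployments_small):
        rate, se = encounter_rate([], deployments_small, bootstrap_reps=100, seed=0)
        assert rate == 0.0

    def test_simple_division(self, deployments_small):
        # 5 cameras x 50 days = 250 cam-days; 25 individuals -> 0.1
        events = [make_sequence(camera=f"cam{k % 5}", n=1) for k in range(25)]
        rate, _ = encounter_rate(events, deployments_small, bootstrap_reps=10, seed=0)
        assert rate == pytest.approx(25 / 250.0)

    def test_bootstrap_se_matches_independent_oracle(self, deployments_small, rng):
        counts = [40, 3, 11, 0, 22]
        events = [
            make_sequence(camera=f"cam{k}") for k, c in enumerate(counts) for _ in range(c)
        ]
        _, se = encounter_rate(events, deployments_small,
                               bootstrap_reps=20000, seed=1)
        y = np.array(counts, dtype=float)
        t = np.full(5, 50.0)
        reps = rng.integers(0, 5, size=(100_000, 5))
        rates = y[reps].sum(axis=1) / t[reps].sum(axis=1)
        oracle = rates.std(ddof=1)
        assert se == pytest.approx(oracle, rel=0.05)

    def test_zero_effort_raises(self):
        with pytest.raises(ValueError):
            encounter_rate([], [], bootstrap_reps=10, seed=0)


class TestDetectionRadius:
    def test_halfnormal_closed_form_edr(self, rng):
        # pdf prop. to u*exp(-u^2/2s^2) is Rayleigh: EDR = sigma*sqrt(2)
        sigma = 4.0
        u = sigma * np.sqrt(-2.0 * np.log(rng.random(10_000)))
        fit = fit_detection_radius(u, truncation=None)
        assert fit.edr == pytest.approx(sigma * math.sqrt(2.0), abs=3 * fit.edr_se)
        assert fit.edr_se < 0.1

    def test_uniform_limit_edr_tends_to_truncation(self, rng):
        # radii piling up near w with g ~ flat: EDR -> w
        u = np.sqrt(rng.random(5000)) * 10.0  # pdf prop. to u on (0, 10]
        fit = fit_detection_radius(u, truncation=10.0)
        assert fit.edr > 9.0

    def test_too_few_radii_raises(self):
        with pytest.raises(ValueError, match="at least"):
            fit_detection_radius([1.0] * 5)

    def test_hazard_rate_key_recovers_its_own_edr(self, rng):
        # rejection-sample radii from pdf prop. to u * g(u) with the
        # hazard-rate detection curve, then check EDR self-recovery
        sigma, b, w = 5.0, 2.5, 15.0
        from scipy.integrate import quad

        def g(u):
            return 1.0 - np.exp(-((u / sigma) ** (-b)))

        u_cand = rng.uniform(0, w, size=200_000)
        keep = rng.random(u_cand.size) < (u_cand / w) * g(u_cand)
        u = u_cand[keep][:5000]
        fit = fit_detection_radius(u, key="hazard", truncation=w)
        area, _ = quad(lambda d: 2 * d * g(d), 0, w, limit=200)
        true_edr = math.sqrt(area)
        assert fit.edr == pytest.approx(true_edr, rel=0.05)


class TestDetectionAngle:
    def test_perfect_detection_returns_full_fov(self, rng):
        fov = 0.9
        angles = rng.uniform(-fov / 2, fov / 2, size=4000)
        theta, _ = fit_detection_angle(angles, fov_rad=fov)
        assert theta == pytest.approx(fov, rel=0.02)

    def test_halfnormal_closed_form(self, rng):
        sig, half = 0.25, 0.6
        from scipy.stats import truncnorm
        a = truncnorm.rvs(0, half / sig, scale=sig, size=20_000, random_state=rng)
        theta, se = fit_detection_angle(a * rng.choice([-1, 1], a.size), fov_rad=2 * half)
        expected = 2.0 * sig * math.sqrt(math.pi / 2) * special.erf(
            half / (math.sqrt(2) * sig)
        )
        assert theta == pytest.approx(expected, abs=max(3 * se, 0.01))


class TestSpeeds:
    def test_unit_conversion_and_zero_path(self):
        ev = [make_sequence(path=10.0, duration=86.4), make_sequence(path=0.0, duration=100.0)]
        s = estimate_speeds(ev)
        assert s[0] == pytest.approx(10.0)
        assert s[1] == 0.0

    def test_batch_equals_elementwise(self, rng):
        paths = rng.uniform(1, 20, 50)
        durs = rng.uniform(5, 300, 50)
        ev = [make_sequence(path=p, duration=d) for p, d in zip(paths, durs)]
        np.testing.assert_allclose(
            estimate_speeds(ev), (paths / 1000.0) / (durs / 86400.0)
        )

    def test_labelled_modes_weighted_mean(self):
        speeds = [10.0] * 30 + [2.0] * 70
        labels = ["run"] * 30 + ["walk"] * 70
        model = fit_behavior_modes(speeds, labels=labels)
        assert model.day_range == pytest.approx(0.3 * 10 + 0.7 * 2)

    def test_single_mode_day_range(self):
        model = fit_behavior_modes([5.638] * 40, labels=["move"] * 40)
        assert model.day_range == pytest.approx(5.638)
        assert model.day_range_se == 0.0

    def test_bic_selects_two_components(self, rng):
        # clearly separated log-normal mixture at n = 500
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(1000 + rep)
            n1 = r.binomial(500, 0.4)
            x = np.concatenate([
                np.exp(r.normal(np.log(2.0), 0.25, n1)),
                np.exp(r.normal(np.log(15.0), 0.25, 500 - n1)),
            ])
            model = fit_behavior_modes(x)
            hits += len(model.modes) == 2
        assert hits >= 18


class TestDensity:
    def test_zero_rate_zero_density(self):
        assert rem_density(_params(rate=0.0)).density == 0.0

    def test_homogeneity(self):
        base = rem_density(_params()).density
        assert rem_density(_params(rate=0.2)).density == pytest.approx(2 * base)
        assert rem_density(_params(v=10.0)).density == pytest.approx(base / 2)
        assert rem_density(_params(r=0.01)).density == pytest.approx(base / 2)
        th = _params().eff_angle_rad
        doubled = _params(theta=2 * (2 + th) - 2)
        assert rem_density(doubled).density == pytest.approx(base / 2)

    def test_invalid_components_raise(self):
        with pytest.raises(ValueError):
            rem_density(_params(v=0.0))
        with pytest.raises(ValueError):
            rem_density(_params(theta=7.0))

    def test_delta_se_single_component(self):
        p = _params(rate=0.1, rate_se=0.01, v_se=0.0, r_se=0.0, theta_se=0.0)
        est = rem_se_delta(p)
        assert est.cv == pytest.approx(0.1)

    def test_delta_se_all_zero(self):
        p = _params(rate_se=0.0, v_se=0.0, r_se=0.0, theta_se=0.0)
        assert rem_se_delta(p).se == 0.0

    def test_missing_se_listed(self):
        with pytest.raises(ValueError, match="day_range"):
            rem_se_delta(_params(rate_se=0.01))

    def test_delta_formula_against_mc_propagation(self, rng):
        # log-normal component errors, CVs <= 0.2
        p = _params(rate=0.15, v=6.0, r=0.005, theta=0.9,
                    rate_se=0.03, v_se=1.0, r_se=0.0005, theta_se=0.1)
        est = rem_se_delta(p)
        n = 1_000_000

        def ln(mean, se):
            s2 = np.log1p((se / mean) ** 2)
            return np.exp(rng.normal(np.log(mean) - s2 / 2, np.sqrt(s2), n))

        d = (ln(0.15, 0.03) * np.pi) / (ln(6.0, 1.0) * ln(0.005, 0.0005)
                                        * (2 + ln(0.9, 0.1)))
        assert est.se == pytest.approx(d.std(), rel=0.1)


class TestSimulatedRecovery:
    def test_simulator_encounter_rate_matches_expectation(self):
        # inverting the density equation at printed worked-example values
        rates = []
        for rep in range(300):
            sim = simulate_rem_events(
                D=6.55, v=5.638, r=0.0049, theta=0.733,
                effort_cam_days=1000.0, seed=rep,
            )
            rates.append(sum(e.n_individuals for e in sim.events) / 1000.0)
        rates = np.asarray(rates)
        expected = 6.55 * 5.638 * 0.0049 * 2.733 / math.pi
        assert expected == pytest.approx(0.158, abs=0.002)  # worked value
        mc_se = rates.std(ddof=1) / math.sqrt(rates.size)
        assert rates.mean() == pytest.approx(expected, abs=3 * mc_se)

    def test_zero_density_zero_events(self):
        sim = simulate_rem_events(D=0.0, v=5.0, r=0.005, theta=0.8, seed=1)
        assert sim.events == []

    def test_single_zero_sd_mode_gives_constant_speed(self):
        sim = simulate_rem_events(
            D=5.0, v=None, r=0.005, theta=0.8, effort_cam_days=500.0,
            speed_modes=[(4.0, 0.0, 1.0)], seed=2,
        )
        speeds = estimate_speeds(sim.events)
        np.testing.assert_allclose(speeds, 4.0, rtol=1e-9)
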