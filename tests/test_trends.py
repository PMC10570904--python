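"""Rank, growth-rate and slope consistency statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctdensity.trends import (
    cv_table,
    density_abundance_regression,
    growth_rates,
    pearson_growth_corr,
    posthoc_slope,
    spearman_test,
    trend_report,
)


class TestSpearman:
    def test_identical_ranking(self):
        s, rho, p = spearman_test([1, 2, 3, 4], [10, 20, 30, 40])
        assert s == 0 and rho == 1.0

    @pytest.mark.parametrize(
        "s_stat,n,expected_rho",
        [(6, 5, 0.70), (30, 14, 0.93), (6, 4, 0.40), (18, 5, 0.10)],
    )
    def test_s_to_rho_identity_on_published_statistics(self, s_stat, n, expected_rho):
        rho = 1.0 - 6.0 * s_stat / (n * (n * n - 1.0))
        assert round(rho, 2) == expected_rho

    def test_statistic_matches_formula_on_random_permutations(self, rng):
        for n in (4, 5, 7):
            for _ in range(20):
                y = rng.permutation(n) + 1.0
                s, rho, _ = spearman_test(np.arange(1.0, n + 1), y)
                assert rho == pytest.approx(1 - 6 * s / (n * (n**2 - 1)))
                # scipy agreement on rho
                assert rho == pytest.approx(
                    stats.spearmanr(np.arange(n), y).statistic
                )

    def test_antisymmetry_under_reversal(self, rng):
        x = np.arange(6.0)
        y = rng.permutation(6).astype(float)
        _, rho_fwd, _ = spearman_test(x, y)
        _, rho_rev, _ = spearman_test(x, y[::-1].copy() * 0 + (-y))
        assert rho_rev == pytest.approx(-rho_fwd)

    def test_s_rho_identity_exhaustive_small_n(self):
        for n in (3, 4, 5):
            base = np.arange(1.0, n + 1)
            for perm in itertools.permutations(base):
                s, rho, _ = spearman_test(base, np.asarray(perm))
                assert rho == pytest.approx(1 - 6 * s / (n * (n * n - 1)))

    def test_exact_p_matches_enumeration(self):
        # n=4: p of perfect agreement = 2/4! (rho = +-1)
        _, _, p = spearman_test([1, 2, 3, 4], [1.0, 2.0, 3.0, 4.0])
        assert p == pytest.approx(2 / 24)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            spearman_test([1, 2], [2, 1])


class TestGrowthRates:
    def test_constant_series(self):
        np.testing.assert_allclose(growth_rates([3.0, 3.0, 3.0]), [1.0, 1.0])

    def test_published_red_deer_ratio(self):
        # consecutive worked values 44.92 -> 25.06
        r = growth_rates([44.92, 25.06])
        assert r[0] == pytest.approx(0.558, abs=0.001)

    def test_gap_years_skipped_not_chained(self):
        series = [1.0, 2.0, 4.0, np.nan, 8.0]
        r = growth_rates(series, years=[1, 2, 3, 4, 5])
        np.testing.assert_allclose(r, [2.0, 2.0])

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            growth_rates([0.0, 1.0])


class TestPearsonGrowth:
    def test_proportional_series(self):
        t, rho, _ = pearson_growth_corr([1, 2, 3], [2.0, 4.0, 6.0])
        assert rho == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "rho,n,expected_t",
        [(0.51, 4, 0.84), (-0.23, 4, -0.33)],
    )
    def test_t_formula_on_published_rhos(self, rho, n, expected_t):
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        assert t == pytest.approx(expected_t, abs=0.01)

    def test_p_matches_scipy(self, rng):
        gx = rng.random(6)
        gy = 0.5 * gx + rng.random(6)
        t, rho, p = pearson_growth_corr(gx, gy)
        ref = stats.pearsonr(gx, gy)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson_growth_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSlope:
    def test_flat_series(self):
        slope, (lo, hi) = posthoc_slope([2.0, 2.0, 2.0, 2.0])
        assert slope == 0.0

    def test_exact_line(self):
        slope, (lo, hi) = posthoc_slope([1.0, 2.0, 3.0, 4.0, 5.0])
        assert slope == pytest.approx(1.0)
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_ols(self, rng):
        y = rng.random(8) * 5
        t = np.arange(1.0, 9)
        slope, _ = posthoc_slope(y)
        beta = np.sum((t - t.mean()) * (y - y.mean())) / np.sum((t - t.mean()) ** 2)
        assert slope == pytest.approx(beta)


class TestCVAndRegression:
    def test_published_fox_cv(self):
        tab = cv_table([0.41], [0.23])
        assert tab.cv[0] == pytest.approx(0.561, abs=0.001)
        assert not tab.precise[0]

    def test_zero_se(self):
        tab = cv_table([2.0], [0.0])
        assert tab.cv[0] == 0.0 and tab.precise[0]

    def test_elementwise_oracle(self, rng):
        est = rng.uniform(0.5, 10, 20)
        se = rng.uniform(0.0, 2, 20)
        tab = cv_table(est, se)
        np.testing.assert_allclose(tab.cv, se / est)

    def test_nonpositive_estimate_flagged(self):
        tab = cv_table([0.0, -1.0], [0.1, 0.1])
        assert tab.cv.isna().all()
        assert not tab.precise.any()

    def test_regression_perfect_proportionality(self):
        a = np.array([1.0, 2, 3, 4])
        slope, intercept, r2 = density_abundance_regression(2 * a, a)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)

    def test_regression_uncorrelated_noise(self):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            _, _, r2 = density_abundance_regression(r.random(100), r.random(100))
            hits += r2 < 0.1
        assert hits >= 36

    def test_r2_matches_sse_sst_oracle(self, rng):
        a = rng.random(30)
        d = 1.5 * a + rng.normal(0, 0.2, 30)
        slope, intercept, r2 = density_abundance_regression(d, a)
        resid = d - (slope * a + intercept)
        sst = np.sum((d - d.mean()) ** 2)
        assert r2 == pytest.approx(1 - np.sum(resid**2) / sst)


class TestReport:
    def test_full_report_structure(self, rng):
        rows_r, rows_n = [], []
        for sp, scale in (("fox", 0.5), ("boar", 6.0), ("deer", 30.0)):
            for year in range(1, 6):
                if sp == "fox" and year == 4:
                    continue  # missing REM year
                est = scale * (1 + 0.2 * rng.standard_normal())
                rows_r.append((sp, year, est, 0.2 * est))
                rows_n.append((sp, year, est * 40 * (1 + 0.1 * rng.standard_normal()),
                               est * 4))
        dens = pd.DataFrame(rows_r, columns=["species", "year", "estimate", "se"])
        abund = pd.DataFrame(rows_n, columns=["species", "year", "estimate", "se"])
        rep = trend_report(dens, abund)
        assert set(rep.spearman.species) == {"community", "fox", "boar", "deer"}
        comm = rep.spearman[rep.spearman.species == "community"].iloc[0]
        n = 14
        assert comm.rho == pytest.approx(1 - 6 * comm.S / (n * (n * n - 1)))
        assert rep.regression["r2"] > 0.8  # strongly proportional by design
        assert {"rem", "nmm"} == set(rep.cv.method)
        # fox growth series has a gap at year 4: only 2 ratios, no fox Pearson
        assert "fox" not in set(rep.pearson_growth.species)
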