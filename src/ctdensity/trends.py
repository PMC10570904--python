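"""Trend-consistency statistics between two yearly estimate series.

Compares density (REM) and abundance (NMM) trajectories three ways:
rank agreement of yearly estimates (Spearman, with the classical
S = sum of squared rank differences statistic), similarity of yearly
growth-rate trajectories x_t / x_{t-1} (Pearson, with its t statistic),
and across-years linear slopes fitted post hoc by least squares.  A CV
table flags which estimates reach management-grade precision
(CV < 0.25).  Missing years are dropped pairwise throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman_test",
    "growth_rates",
    "pearson_growth_corr",
    "posthoc_slope",
    "cv_table",
    "density_abundance_regression",
    "TrendReport",
    "trend_report",
]

CV_THRESHOLD = 0.25


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


@lru_cache(maxsize=None)
def _exact_s_distribution(n: int) -> np.ndarray:
    """Null distribution of S = sum d_i^2 over all n! rank permutations."""
    base = np.arange(1, n + 1)
    return np.sort(
        [int(np.sum((base - np.asarray(p)) ** 2)) for p in itertools.permutations(base)]
    )


def spearman_test(x, y) -> tuple[float, float, float]:
    """Spearman rank correlation as (S, rho, p).

    S is the sum of squared rank differences; for untied data
    rho = 1 - 6 S / (n (n^2 - 1)) and the two-sided p-value is exact
    (full permutation enumeration) for n <= 9, asymptotic otherwise.
    Ties fall back to average ranks with rho as Pearson-on-ranks; S is
    then reported from the average ranks.
    """
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    s = float(np.sum((rx - ry) ** 2))
    tied = (np.unique(x).size < n) or (np.unique(y).size < n)
    if tied:
        rho = float(stats.pearsonr(rx, ry).statistic)
        p = float(stats.spearmanr(x, y).pvalue)
        return s, rho, p
    rho = 1.0 - 6.0 * s / (n * (n * n - 1.0))
    if n <= 9:
        dist = _exact_s_distribution(n)
        mid = n * (n * n - 1.0) / 6.0  # S value at rho = 0
        # two-sided: as or more extreme in |rho| <=> |S - mid| >= |s - mid|
        p = float(np.mean(np.abs(dist - mid) >= abs(s - mid) - 1e-9))
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return s, float(rho), p


def growth_rates(series, years=None) -> np.ndarray:
    """Yearly growth rates x_t / x_{t-1} for consecutive available years.

    ``series`` may contain NaN for missing years; pairs spanning a gap
    are skipped, not chained.  Zero denominators raise.
    """
    x = np.asarray(series, dtype=float)
    t = np.arange(len(x)) if years is None else np.asarray(years)
    rates = []
    for k in range(1, len(x)):
        if t[k] - t[k - 1] != 1:
            continue
        if not (np.isfinite(x[k]) and np.isfinite(x[k - 1])):
            continue
        if x[k - 1] == 0:
            raise ValueError("zero denominator in growth rate")
        rates.append(x[k] / x[k - 1])
    return np.asarray(rates)


def pearson_growth_corr(gx, gy) -> tuple[float, float, float]:
    """Pearson correlation of two growth-rate series as (t, rho, p)."""
    gx, gy = _pairwise_complete(gx, gy)
    n = gx.size
    if n < 3:
        raise ValueError("need at least 3 paired growth rates")
    if np.std(gx) == 0 or np.std(gy) == 0:
        raise ValueError("zero variance in a growth-rate series")
    rho = float(stats.pearsonr(gx, gy).statistic)
    t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return t, rho, p


def posthoc_slope(series, years=None, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """OLS slope of yearly estimates on year index, with a t-based CI."""
    y = np.asarray(series, dtype=float)
    t = (np.arange(1, len(y) + 1) if years is None else np.asarray(years)).astype(float)
    t, y = _pairwise_complete(t, y)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 points for a slope")
    res = stats.linregress(t, y)
    half = stats.t.ppf(0.5 + level / 2.0, n - 2) * res.stderr
    return float(res.slope), (float(res.slope - half), float(res.slope + half))


def cv_table(estimates, ses, labels=None) -> pd.DataFrame:
    """CV = SE / estimate per series entry, flagged against CV < 0.25.

    Non-positive point estimates yield an undefined (NaN) CV, flagged.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(est > 0, se / est, np.nan)
    return pd.DataFrame(
        {
            "label": labels if labels is not None else np.arange(est.size),
            "estimate": est,
            "se": se,
            "cv": cv,
            "precise": (cv < CV_THRESHOLD) & np.isfinite(cv),
        }
    )


def density_abundance_regression(densities, abundances) -> tuple[float, float, float]:
    """OLS of density on abundance pooled over species-years: (slope, intercept, R^2)."""
    a, d = _pairwise_complete(abundances, densities)
    if d.size < 3:
        raise ValueError("need at least 3 paired estimates")
    res = stats.linregress(a, d)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


@dataclass
class TrendReport:
    """Per-species and community trend-consistency summaries."""

    spearman: pd.DataFrame       # species, S, rho, p
    pearson_growth: pd.DataFrame  # species, t, rho, p
    slopes: pd.DataFrame         # series, species, slope, lo, hi
    regression: dict             # slope, intercept, r2
    cv: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "spearman": self.spearman.to_dict(orient="records"),
            "pearson_growth": self.pearson_growth.to_dict(orient="records"),
            "slopes": self.slopes.to_dict(orient="records"),
            "regression": self.regression,
            "cv": self.cv.to_dict(orient="records"),
        }


def trend_report(
    densities: pd.DataFrame,
    abundances: pd.DataFrame,
) -> TrendReport:
    """Full consistency report between REM densities and NMM abundances.

    Both inputs are long frames with columns (species, year, estimate,
    se); missing species-years may be absent or NaN.  The community
    Spearman pools all species-year pairs; growth-rate correlations are
    per species and pooled.
    """
    merged = densities.merge(
        abundances, on=["species", "year"], suffixes=("_rem", "_nmm"), how="inner"
    ).dropna(subset=["estimate_rem", "estimate_nmm"])

    sp_rows = [("community", *spearman_test(merged["estimate_nmm"], merged["estimate_rem"]))]
    pg_rows = []
    slope_rows = []
    all_gd, all_ga = [], []
    for sp, sub in merged.groupby("species", sort=True):
        sub = sub.sort_values("year")
        if len(sub) >= 3:
            sp_rows.append((sp, *spearman_test(sub["estimate_nmm"], sub["estimate_rem"])))
            slope, (lo, hi) = posthoc_slope(sub["estimate_rem"], sub["year"])
            slope_rows.append(("rem", sp, slope, lo, hi))
            slope, (lo, hi) = posthoc_slope(sub["estimate_nmm"], sub["year"])
            slope_rows.append(("nmm", sp, slope, lo, hi))
        gd = growth_rates(sub["estimate_rem"].to_numpy(), sub["year"].to_numpy())
        ga = growth_rates(sub["estimate_nmm"].to_numpy(), sub["year"].to_numpy())
        all_gd.append(gd)
        all_ga.append(ga)
        if gd.size >= 3:
            pg_rows.append((sp, *pearson_growth_corr(gd, ga)))
    gd = np.concatenate(all_gd) if all_gd else np.array([])
    ga = np.concatenate(all_ga) if all_ga else np.array([])
    if gd.size >= 3:
        pg_rows.insert(0, ("community", *pearson_growth_corr(gd, ga)))

    slope_m, intercept, r2 = density_abundance_regression(
        merged["estimate_rem"], merged["estimate_nmm"]
    )
    cv_frames = []
    for tag, est_col, se_col in (
        ("rem", "estimate_rem", "se_rem"),
        ("nmm", "estimate_nmm", "se_nmm"),
    ):
        tab = cv_table(
            merged[est_col],
            merged[se_col],
            labels=[f"{s}:{y}" for s, y in zip(merged["species"], merged["year"])],
        )
        tab.insert(0, "method", tag)
        cv_frames.append(tab)

    return TrendReport(
        spearman=pd.DataFrame(sp_rows, columns=["species", "S", "rho", "p"]),
        pearson_growth=pd.DataFrame(pg_rows, columns=["species", "t", "rho", "p"]),
        slopes=pd.DataFrame(
            slope_rows, columns=["method", "species", "slope", "ci_lo", "ci_hi"]
        ),
        regression={"slope": slope_m, "intercept": intercept, "r2": r2},
        cv=pd.concat(cv_frames, ignore_index=True),
    )
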