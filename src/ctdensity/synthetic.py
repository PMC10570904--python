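"""Synthetic camera-trap surveys with known ground truth.

Two generators mirror the two analysis paradigms:

* :func:`simulate_counts` draws a daily count table from the exact
  generative structure the N-mixture model assumes — Poisson latent
  abundance with log-linear predictors, GP year curves, an (exact, not
  reduced-rank) squared-exponential spatial field, and beta-distributed
  species detection rates;
* :func:`simulate_rem_events` draws event-level encounter data whose
  expected encounter rate inverts the REM density equation, with entry
  radii from a half-normal point-process detection model, angles from a
  uniform field of view thinned by a half-normal, and speeds from a
  log-normal behaviour mixture.

Every public function takes an explicit integer seed and uses its own
PCG64 generator; no global random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from ._gp import chol_corr, sqexp_kernel
from .counts import CountTable
from .io import Deployment, SequenceRecord

__all__ = [
    "SurveyDesign",
    "CountSimParams",
    "SimulationTruth",
    "REMSimulation",
    "simulate_gp_curve",
    "simulate_counts",
    "simulate_rem_events",
    "default_site_coords",
]


def simulate_gp_curve(
    n_points: int, marginal_sd: float, lengthscale: float, seed: int | np.random.Generator
) -> np.ndarray:
    """One draw from a zero-mean squared-exponential GP on 1..n_points."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if lengthscale <= 0:
        raise ValueError("lengthscale must be positive")
    if marginal_sd < 0:
        raise ValueError("marginal_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if marginal_sd == 0.0:
        return np.zeros(n_points)
    x = np.arange(1, n_points + 1, dtype=float)
    L = chol_corr(x, lengthscale)
    return marginal_sd * (L @ rng.standard_normal(n_points))


def default_site_coords(n_sites: int, spacing_km: float = 1.0) -> np.ndarray:
    """A square lattice of site centroids (camera-grid-like layout)."""
    side = math.ceil(math.sqrt(n_sites))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float) * spacing_km
    return coords[:n_sites]


@dataclass
class SurveyDesign:
    """Survey dimensions for the count simulator."""

    n_sites: int = 25
    n_years: int = 4
    days_per_year: int = 20
    site_coords: np.ndarray | None = None
    effort: np.ndarray | None = None  # (R, J, T) bool; full effort if None

    def coords(self) -> np.ndarray:
        if self.site_coords is not None:
            return np.asarray(self.site_coords, dtype=float)
        return default_site_coords(self.n_sites)

    def effort_mask(self) -> np.ndarray:
        if self.effort is not None:
            return np.asarray(self.effort, dtype=bool)
        return np.ones((self.n_sites, self.days_per_year, self.n_years), dtype=bool)


@dataclass
class CountSimParams:
    """Generative parameters for the count simulator.

    Defaults emulate a three-species community of a scavenger, a
    medium-density and a high-density ungulate surveyed by ~20-30
    cameras over a handful of winters: expected site abundances around
    0.5, 2 and 7.5; a community detection rate drifting on the logit
    scale between years; moderate similarity of species detection rates
    (tau); small species trend noise; spatial field off unless asked.
    """

    beta0: np.ndarray = field(default_factory=lambda: np.log([0.5, 2.0, 7.5]))
    beta1: np.ndarray | None = None
    det_gp_sd: float = 0.75
    det_gp_ls: float = 2.0
    tau: float = 5.0
    trend_gp_sd: float = 0.25
    trend_gp_ls: float = 1.5
    spatial_sd: float = 0.0
    spatial_ls: float = 1.5
    p_st: np.ndarray | None = None  # explicit (S, T) detection rates


@dataclass
class SimulationTruth:
    """Everything the generator drew, for parameter-recovery checks."""

    lam: np.ndarray       # (S, R, T)
    N: np.ndarray         # (S, R, T)
    p_t: np.ndarray       # (T,)
    p_st: np.ndarray      # (S, T)
    tau: float
    beta0: np.ndarray
    beta1: np.ndarray | None
    f: np.ndarray         # (T,) logit community detection curve
    g: np.ndarray         # (S, T) species trend-noise curves
    spatial: np.ndarray   # (S, R)
    seed: int | None


def simulate_counts(
    design: SurveyDesign,
    params: CountSimParams | None = None,
    detection_family: str = "poisson",
    seed: int = 0,
) -> tuple[SimulationTruth, CountTable]:
    """Draw a daily count table from the N-mixture generative model.

    log lambda_sit = beta0_s [+ beta1_s * t] + g_s(t) + spatial_s(i);
    N_sit ~ Poisson(lambda_sit); y_sijt ~ Poisson(N * p_st) (Poisson
    family; p_st acts as a per-individual daily detection *rate*, and
    may exceed 1 when given explicitly) or Binomial(N, p_st).
    """
    if detection_family not in ("poisson", "binomial"):
        raise ValueError(f"unknown detection_family {detection_family!r}")
    params = params or CountSimParams()
    rng = np.random.default_rng(seed)

    beta0 = np.asarray(params.beta0, dtype=float)
    S = beta0.size
    R, J, T = design.n_sites, design.days_per_year, design.n_years
    coords = design.coords()
    mask = design.effort_mask()

    f = simulate_gp_curve(T, params.det_gp_sd, params.det_gp_ls, rng)
    p_t = special.expit(f)
    if params.p_st is not None:
        p_st = np.asarray(params.p_st, dtype=float)
        if p_st.shape != (S, T):
            raise ValueError("explicit p_st must have shape (S, T)")
    else:
        a = p_t * params.tau
        b = (1.0 - p_t) * params.tau
        p_st = rng.beta(a[None, :], b[None, :], size=(S, T))
    if detection_family == "binomial" and np.any((p_st <= 0) | (p_st >= 1)):
        raise ValueError("binomial detection requires p_st in (0, 1)")

    g = np.stack(
        [simulate_gp_curve(T, params.trend_gp_sd, params.trend_gp_ls, rng) for _ in range(S)]
    )
    if params.spatial_sd > 0:
        K = sqexp_kernel(coords, params.spatial_sd, params.spatial_ls)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(R))
        spatial = (L @ rng.standard_normal((R, S))).T
    else:
        spatial = np.zeros((S, R))

    t_idx = np.arange(1, T + 1, dtype=float)
    t_std = t_idx - t_idx.mean()
    log_lam = beta0[:, None, None] + g[:, None, :] + spatial[:, :, None]
    beta1 = None
    if params.beta1 is not None:
        beta1 = np.asarray(params.beta1, dtype=float)
        log_lam = log_lam + beta1[:, None, None] * t_std[None, None, :]
    lam = np.exp(log_lam)                     # (S, R, T)

    N = rng.poisson(lam)
    mean = N[:, :, None, :] * p_st[:, None, None, :]
    if detection_family == "poisson":
        y = rng.poisson(np.broadcast_to(mean, (S, R, J, T)))
    else:
        y = rng.binomial(
            np.broadcast_to(N[:, :, None, :], (S, R, J, T)),
            np.broadcast_to(p_st[:, None, None, :], (S, R, J, T)),
        )
    y = np.where(mask[None], y, 0)

    truth = SimulationTruth(
        lam=lam, N=N, p_t=p_t, p_st=p_st, tau=params.tau, beta0=beta0, beta1=beta1,
        f=f, g=g, spatial=spatial, seed=seed,
    )
    table = CountTable(
        counts=y,
        effort=mask,
        species=[f"sp{k + 1}" for k in range(S)],
        site_ids=list(range(R)),
        site_coords=coords,
        years=list(range(1, T + 1)),
    )
    return truth, table


# ---------------------------------------------------------------------------
# REM event simulator

@dataclass
class REMSimulation:
    """Events plus the deployments and generating truth."""

    events: list[SequenceRecord]
    deployments: list[Deployment]
    density: float
    day_range: float
    eff_radius_km: float
    eff_angle_rad: float
    sigma_radius_km: float
    half_fov_rad: float
    r_max_km: float
    seed: int | None


def _solve_sigma_radius(r: float, r_max: float) -> float:
    """Half-normal scale whose truncated EDR equals the requested radius."""
    if not r < r_max:
        raise ValueError("effective radius must be below the truncation radius")

    def edr(sigma):
        return math.sqrt(2.0 * sigma**2 * (1.0 - math.exp(-(r_max**2) / (2 * sigma**2))))

    return float(optimize.brentq(lambda s: edr(s) - r, r / 2.0, 50.0 * r, xtol=1e-14))


def _solve_half_fov(theta: float, sigma_angle: float) -> float:
    """Field-of-view half-angle whose effective angle equals theta."""
    sup = sigma_angle * math.sqrt(2.0 * math.pi)
    if theta >= sup:
        raise ValueError(
            f"requested effective angle {theta} unattainable: half-normal "
            f"angle thinning with sigma_angle={sigma_angle} caps it at {sup:.4f}"
        )

    def eff(A):
        return 2.0 * sigma_angle * math.sqrt(math.pi / 2.0) * special.erf(
            A / (math.sqrt(2.0) * sigma_angle)
        )

    return float(
        optimize.brentq(lambda A: eff(A) - theta, theta / 2.0, 50.0 * sigma_angle,
                        xtol=1e-14)
    )


def simulate_rem_events(
    D: float,
    v: float | None = None,
    r: float = 0.005,
    theta: float = 0.8,
    effort_cam_days: float = 1000.0,
    sigma_angle: float = 0.5,
    speed_modes: Sequence[tuple[float, float, float]] | None = None,
    seed: int = 0,
    n_cameras: int = 20,
    r_max_km: float | None = None,
    species: str = "sp1",
) -> REMSimulation:
    """Draw event-level encounter data at the REM-implied rate.

    The encounter count is Poisson with mean D*v*r*(2+theta)/pi *
    effort; the day range v is the weight-averaged mean of the
    log-normal speed modes ``(mean km/day, sd, weight)`` (modes are
    rescaled to an explicitly requested ``v``).  Each event records an
    entry radius (half-normal point-process detection truncated at
    ``r_max_km``), an entry angle (uniform field of view thinned
    half-normally, symmetric about the axis) and a traversal
    path/duration implying its speed; its generating mode is carried as
    the behaviour label.
    """
    if D < 0 or r <= 0 or theta <= 0 or effort_cam_days <= 0:
        raise ValueError("D must be >= 0 and r, theta, effort positive")
    if speed_modes is None:
        base_v = v if v is not None else 6.0
        speed_modes = [(base_v, 0.3 * base_v, 1.0)]
    wsum = sum(m[2] for m in speed_modes)
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError("speed-mode weights must sum to 1")
    mode_means = np.array([m[0] for m in speed_modes], dtype=float)
    mode_sds = np.array([m[1] for m in speed_modes], dtype=float)
    mode_w = np.array([m[2] for m in speed_modes], dtype=float)
    if v is not None:
        scale = v / float(mode_w @ mode_means)
        mode_means, mode_sds = mode_means * scale, mode_sds * scale
    v_true = float(mode_w @ mode_means)

    r_max = r_max_km if r_max_km is not None else 2.5 * r
    sigma_r = _solve_sigma_radius(r, r_max)
    half_fov = _solve_half_fov(theta, sigma_angle)

    rng = np.random.default_rng(seed)
    n_events = rng.poisson(D * v_true * r * (2.0 + theta) / math.pi * effort_cam_days)

    per_cam = effort_cam_days / n_cameras
    start = pd.Timestamp("2020-01-01")
    end = start + pd.Timedelta(days=per_cam)
    deployments = [
        Deployment(
            camera_id=f"cam{c:02d}",
            x_km=float(c % 5) * 2.0,
            y_km=float(c // 5) * 2.0,
            start=start,
            end=end,
            year_index=1,
        )
        for c in range(n_cameras)
    ]

    # inverse-CDF sampling of radii: CDF prop. to 1 - exp(-u^2/2s^2), truncated
    u = rng.random(n_events)
    trunc_mass = 1.0 - math.exp(-(r_max**2) / (2.0 * sigma_r**2))
    radii_km = sigma_r * np.sqrt(-2.0 * np.log1p(-u * trunc_mass))

    abs_angles = stats.truncnorm.rvs(
        0.0, half_fov / sigma_angle, loc=0.0, scale=sigma_angle,
        size=n_events, random_state=rng,
    )
    angles = abs_angles * rng.choice([-1.0, 1.0], size=n_events)

    modes = rng.choice(len(mode_w), p=mode_w, size=n_events)
    mu = np.log(np.maximum(mode_means, 1e-300)) - 0.5 * np.log1p(
        (mode_sds / np.maximum(mode_means, 1e-300)) ** 2
    )
    sig = np.sqrt(np.log1p((mode_sds / np.maximum(mode_means, 1e-300)) ** 2))
    speeds = np.exp(mu[modes] + sig[modes] * rng.standard_normal(n_events))

    cams = rng.integers(0, n_cameras, size=n_events)
    offsets = rng.random(n_events) * per_cam
    paths_m = rng.uniform(3.0, 10.0, size=n_events)
    # duration from speed: speed km/day -> m/s = *1000/86400
    durations_s = paths_m / (speeds * 1000.0 / 86400.0)

    events = [
        SequenceRecord(
            species=species,
            camera_id=f"cam{cams[k]:02d}",
            start_time=start + pd.Timedelta(days=float(offsets[k])),
            n_individuals=1,
            entry_radius_m=float(radii_km[k] * 1000.0),
            entry_angle_rad=float(angles[k]),
            path_length_m=float(paths_m[k]),
            duration_s=float(durations_s[k]),
            behaviour=f"mode{modes[k]}",
        )
        for k in range(n_events)
    ]
    return REMSimulation(
        events=events,
        deployments=deployments,
        density=D,
        day_range=v_true,
        eff_radius_km=r,
        eff_angle_rad=theta,
        sigma_radius_km=sigma_r,
        half_fov_rad=half_fov,
        r_max_km=r_max,
        seed=seed,
    )
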