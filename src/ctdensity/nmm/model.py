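"""Joint posterior of the multi-species N-mixture model.

Generative structure (species s, site i, day j, year t):

    y_sijt | N_sit ~ Poisson(N_sit * p_st)   [or Binomial(N_sit, p_st)]
    p_st ~ Beta(p_t * tau, (1 - p_t) * tau);  logit(p_t) = f(t)
    N_sit ~ Poisson(lambda_sit)
    log lambda_sit = beta_s0 [+ beta_s1 * t] + g_s(t) + h_s(x_i)

with f and g_s zero-mean squared-exponential GPs over the (centred)
year index and h_s a reduced-rank GP spatial field.  The latent N are
marginalized to a per-species bound K_s = max(y) + 100 by default.

The unconstrained parameter vector uses non-centred GP weights and log/
logit transforms throughout; :meth:`NMixtureModel.logp_and_grad`
returns the exact joint log-density and its analytic gradient (checked
against finite differences in the test-suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.special import digamma, expit, gammaln, log_expit

from .._gp import chol_corr_dlength_from_d2
from ..counts import CountTable
from .hsgp import HSGPBasis, hsgp_basis
from .likelihood import SpeciesCounts, scan_units as _scan

__all__ = ["PriorConfig", "NMMSpec", "NMixtureModel"]


@dataclass
class PriorConfig:
    """Package-default weakly-informative priors (all overridable).

    Scales: Normal(0, beta_sd) on intercepts/slopes; half-Normal on GP
    marginal SDs and on the detection-similarity tau; log-normal on
    lengthscales, centred on half the time-series span (year GPs) or on
    half the spatial half-width (HSGP) when not given explicitly.
    """

    beta_sd: float = 2.0
    gp_sd_scale: float = 1.0
    ls_mu: float | None = None
    ls_sigma: float = 0.5
    tau_scale: float = 5.0
    sp_sd_scale: float = 1.0
    sp_ls_mu: float | None = None
    sp_ls_sigma: float = 0.75


@dataclass
class NMMSpec:
    """Model variant, truncation, basis and MCMC settings."""

    variant: str = "M1"                  # M1 (no linear trend) | M2
    spatial: bool = False
    detection_family: str = "poisson"    # poisson | binomial
    K: dict[str, int] | None = None      # per-species truncation; default max(y)+100
    m_basis: int = 20                    # HSGP basis functions per dimension
    c_boundary: float = 1.5
    priors: PriorConfig = dfield(default_factory=PriorConfig)
    chains: int = 2
    iterations: int = 10_000             # total per chain, warmup included
    warmup: int = 5_000
    thin: int = 1                        # keep every thin-th post-warmup draw
    seed: int = 0
    target_accept: float = 0.93
    metric: str = "auto"                 # auto | dense | diag
    # one exploratory chain adapts the metric which all sampling chains
    # then share; removes between-chain adaptation disparity
    shared_adaptation: bool = True
    # re-run a non-converged fit with a fresh derived seed up to this
    # many times (the standard practitioner response to a failed R-hat
    # check at short chain lengths); 0 disables
    max_restarts: int = 0
    # parameterization of the GP/beta blocks; the non-centred default
    # samples far better at the survey sizes this model targets
    center_g: bool = False
    center_p: bool = False

    def __post_init__(self) -> None:
        if self.variant not in ("M1", "M2"):
            raise ValueError("variant must be 'M1' or 'M2'")
        if self.detection_family not in ("poisson", "binomial"):
            raise ValueError("detection_family must be 'poisson' or 'binomial'")
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")


class NMixtureModel:
    """Marginalized joint posterior with analytic gradients."""

    def __init__(self, counts: CountTable, spec: NMMSpec):
        self.spec = spec
        self.counts = counts
        S, R, J, T = counts.counts.shape
        self.S, self.R, self.T = S, R, T
        if T < 2:
            raise ValueError("need at least 2 years for the GP year curves")

        self.species_data = []
        for s, name in enumerate(counts.species):
            K = None if spec.K is None else spec.K.get(name)
            self.species_data.append(
                SpeciesCounts.from_arrays(
                    counts.counts[s], counts.effort, K=K,
                    family=spec.detection_family,
                )
            )

        t_idx = np.arange(1, T + 1, dtype=float)
        self.t_std = t_idx - t_idx.mean()
        self._year_d2 = (t_idx[:, None] - t_idx[None, :]) ** 2

        # ---- merged per-unit arrays across species (single kernel call);
        # the constant blocks are padded to the largest K with -inf, which
        # the early-terminating scan never reaches
        Kmax = max(sd.K for sd in self.species_data)
        blocks = []
        for sd in self.species_data:
            C0 = sd._const_block()
            if sd.K < Kmax:
                pad = np.full((C0.shape[0], Kmax - sd.K), -np.inf)
                C0 = np.hstack([C0, pad])
            blocks.append(C0)
        self._m_C0 = np.ascontiguousarray(np.vstack(blocks))
        self._m_sp = np.concatenate(
            [np.full(sd.n_units, s) for s, sd in enumerate(self.species_data)]
        )
        self._m_site = np.concatenate([sd.site_idx for sd in self.species_data])
        self._m_year = np.concatenate([sd.year_idx for sd in self.species_data])
        self._m_total = np.concatenate([sd.total for sd in self.species_data]).astype(float)
        self._m_ndays = np.concatenate([sd.n_days for sd in self.species_data]).astype(float)
        self._m_lognorm = np.concatenate([sd.log_norm for sd in self.species_data])
        self._m_spT = self._m_sp * T + self._m_year
        self._m_spR = self._m_sp * R + self._m_site
        self._m_tstd = self.t_std[self._m_year]
        self._n_units_total = self._m_sp.size

        pr = spec.priors
        self.ls_mu = pr.ls_mu if pr.ls_mu is not None else np.log(max(T / 2.0, 1.0))
        self.basis: HSGPBasis | None = None
        if spec.spatial:
            self.basis = hsgp_basis(counts.site_coords, m=spec.m_basis, c=spec.c_boundary)
            hw = float(np.mean(self.basis.L / spec.c_boundary))
            self.sp_ls_mu = (
                pr.sp_ls_mu if pr.sp_ls_mu is not None else np.log(max(0.5 * hw, 1e-3))
            )

        # ---- unconstrained layout ----------------------------------------
        self.layout: dict[str, slice] = {}
        pos = 0

        def block(name: str, size: int) -> None:
            nonlocal pos
            self.layout[name] = slice(pos, pos + size)
            pos += size

        block("z_f", T)
        block("log_sd_f", 1)
        block("log_ls_f", 1)
        block("log_tau", 1)
        if spec.center_p:
            # logit p_st sampled directly
            block("xp", S * T)
        else:
            # non-centred: logit p_st = f_t + u_st / sqrt(tau), flattening
            # the similarity funnel (large tau pins p_st to p_t)
            block("u_p", S * T)
        block("b0", S)
        if spec.variant == "M2":
            block("b1", S)
        if spec.center_g:
            block("g", S * T)
        else:
            block("z_g", S * T)
        block("log_sd_g", 1)
        block("log_ls_g", 1)
        if spec.spatial:
            M = self.basis.n_basis
            block("w_sp", S * M)
            block("log_sd_sp", S)
            block("log_ls_sp", 1)
        self.dim = pos
        self._build_fused_args()

    def _build_fused_args(self) -> None:
        """Constant argument pack for the compiled evaluation kernel."""
        from ._fused import HAVE_FUSED

        self._use_fused = HAVE_FUSED
        if not HAVE_FUSED:
            return
        spec, pr = self.spec, self.spec.priors
        lay = self.layout
        name_p = "xp" if spec.center_p else "u_p"
        name_g = "g" if spec.center_g else "z_g"
        offs = np.array(
            [
                lay["z_f"].start, lay["log_sd_f"].start, lay["log_ls_f"].start,
                lay["log_tau"].start, lay[name_p].start, lay["b0"].start,
                lay["b1"].start if spec.variant == "M2" else 0,
                lay[name_g].start, lay["log_sd_g"].start, lay["log_ls_g"].start,
                lay["w_sp"].start if spec.spatial else 0,
                lay["log_sd_sp"].start if spec.spatial else 0,
                lay["log_ls_sp"].start if spec.spatial else 0,
            ],
            dtype=np.int64,
        )
        flags = np.array(
            [
                spec.variant == "M2", spec.spatial, spec.center_p,
                spec.center_g, spec.detection_family == "binomial",
            ],
            dtype=np.int64,
        )
        priors = np.array(
            [
                pr.beta_sd, pr.gp_sd_scale, self.ls_mu, pr.ls_sigma,
                pr.tau_scale, pr.sp_sd_scale,
                self.sp_ls_mu if spec.spatial else 0.0,
                pr.sp_ls_sigma, 1e-10,
            ],
            dtype=np.float64,
        )
        if spec.spatial:
            dims = np.array([self.S, self.R, self.T, self.basis.n_basis],
                            dtype=np.int64)
            phi = np.ascontiguousarray(self.basis.phi)
            omega2 = self.basis.omega2
        else:
            dims = np.array([self.S, self.R, self.T, 0], dtype=np.int64)
            phi = np.zeros((1, 1))
            omega2 = np.zeros(1)
        self._fused_args = (
            offs, flags, priors, dims,
            np.ascontiguousarray(self._year_d2), self.t_std,
            self._m_C0, self._m_sp, self._m_site, self._m_year,
            self._m_spT, self._m_spR,
            self._m_total, self._m_ndays, self._m_lognorm, self._m_tstd,
            phi, omega2,
        )

    # -- helpers ------------------------------------------------------------

    def _get(self, theta: np.ndarray, name: str) -> np.ndarray:
        return theta[self.layout[name]]

    def unit_labels(self) -> list[tuple[str, int, int]]:
        """(species, site id, year) per pointwise-likelihood unit."""
        labels = []
        for s, name in enumerate(self.counts.species):
            sd = self.species_data[s]
            for i, t in zip(sd.site_idx, sd.year_idx):
                labels.append(
                    (name, self.counts.site_ids[i], self.counts.years[t])
                )
        return labels

    @property
    def n_units(self) -> int:
        return sum(sd.n_units for sd in self.species_data)

    def _forward(self, theta: np.ndarray) -> dict:
        """Constrained quantities needed by both logp and summaries."""
        S, R, T = self.S, self.R, self.T
        sd_f = np.exp(self._get(theta, "log_sd_f")[0])
        ls_f = np.exp(self._get(theta, "log_ls_f")[0])
        sd_g = np.exp(self._get(theta, "log_sd_g")[0])
        ls_g = np.exp(self._get(theta, "log_ls_g")[0])
        tau = np.exp(self._get(theta, "log_tau")[0])
        z_f = self._get(theta, "z_f")
        b0 = self._get(theta, "b0")
        b1 = self._get(theta, "b1") if self.spec.variant == "M2" else None

        L_f, dL_f = chol_corr_dlength_from_d2(self._year_d2, ls_f)
        f = sd_f * (L_f @ z_f)
        p_t = expit(f)

        u_p = None
        if self.spec.center_p:
            xp = self._get(theta, "xp").reshape(S, T)
        else:
            u_p = self._get(theta, "u_p").reshape(S, T)
            xp = f[None, :] + u_p / np.sqrt(tau)
        p_st = expit(xp)

        Z_g = L_g = dL_g = None
        if self.spec.center_g:
            G = self._get(theta, "g").reshape(S, T)
        else:
            Z_g = self._get(theta, "z_g").reshape(S, T)
            L_g, dL_g = chol_corr_dlength_from_d2(self._year_d2, ls_g)
            G = sd_g * (Z_g @ L_g.T)

        log_lam = np.broadcast_to(b0[:, None, None], (S, R, T)).copy()
        log_lam += G[:, None, :]
        if b1 is not None:
            log_lam += b1[:, None, None] * self.t_std[None, None, :]

        out = dict(
            sd_f=sd_f, ls_f=ls_f, sd_g=sd_g, ls_g=ls_g, tau=tau,
            z_f=z_f, u_p=u_p, xp=xp, b0=b0, b1=b1, Z_g=Z_g,
            L_f=L_f, dL_f=dL_f, L_g=L_g, dL_g=dL_g,
            f=f, G=G, p_t=p_t, p_st=p_st,
        )
        if self.spec.spatial:
            M = self.basis.n_basis
            W = self._get(theta, "w_sp").reshape(S, M)
            sd_sp = np.exp(self._get(theta, "log_sd_sp"))
            ls_sp = np.exp(self._get(theta, "log_ls_sp")[0])
            Q = self.basis.sqrt_spd(ls_sp)
            SP = sd_sp[:, None] * ((W * Q[None, :]) @ self.basis.phi.T)  # (S, R)
            log_lam += SP[:, :, None]
            out.update(W=W, sd_sp=sd_sp, ls_sp=ls_sp, Q=Q, SP=SP)
        out["log_lam"] = log_lam
        return out

    # -- log density and gradient -------------------------------------------

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Joint log-density and gradient (compiled path when available)."""
        if self._use_fused:
            from ._fused import fused_logp_grad

            return fused_logp_grad(self, theta)
        return self._logp_and_grad_numpy(theta)

    def _logp_and_grad_numpy(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        S, R, T = self.S, self.R, self.T
        spec = self.spec
        pr = spec.priors
        lay = self.layout
        grad = np.zeros_like(theta)
        logp = 0.0

        # ---- forward pass (inline; see _forward for the readable form) ----
        sd_f = np.exp(theta[lay["log_sd_f"]][0])
        ls_f = np.exp(theta[lay["log_ls_f"]][0])
        sd_g = np.exp(theta[lay["log_sd_g"]][0])
        ls_g = np.exp(theta[lay["log_ls_g"]][0])
        tau = np.exp(theta[lay["log_tau"]][0])
        z_f = theta[lay["z_f"]]
        b0 = theta[lay["b0"]]
        b1 = theta[lay["b1"]] if spec.variant == "M2" else None

        L_f, dL_f = chol_corr_dlength_from_d2(self._year_d2, ls_f)
        f = sd_f * (L_f @ z_f)
        p_t = expit(f)

        if spec.center_p:
            xp = theta[lay["xp"]].reshape(S, T)
        else:
            u_p = theta[lay["u_p"]].reshape(S, T)
            xp = f[None, :] + u_p / np.sqrt(tau)
        p_st = expit(xp)

        if spec.center_g:
            G = theta[lay["g"]].reshape(S, T)
        else:
            Z_g = theta[lay["z_g"]].reshape(S, T)
            L_g, dL_g = chol_corr_dlength_from_d2(self._year_d2, ls_g)
            G = sd_g * (Z_g @ L_g.T)

        loglam_u = b0[self._m_sp] + G.ravel()[self._m_spT]
        if b1 is not None:
            loglam_u = loglam_u + b1[self._m_sp] * self._m_tstd
        if spec.spatial:
            M = self.basis.n_basis
            W = theta[lay["w_sp"]].reshape(S, M)
            sd_sp = np.exp(theta[lay["log_sd_sp"]])
            ls_sp = np.exp(theta[lay["log_ls_sp"]][0])
            Q = self.basis.sqrt_spd(ls_sp)
            SP = sd_sp[:, None] * ((W * Q[None, :]) @ self.basis.phi.T)  # (S, R)
            loglam_u = loglam_u + SP.ravel()[self._m_spR]

        # ---- marginalized likelihood over all units in one kernel pass ----
        p_u = p_st.ravel()[self._m_spT]
        lam_u = np.exp(loglam_u)
        binom = spec.detection_family == "binomial"
        with np.errstate(divide="ignore", invalid="ignore"):
            if binom:
                l1p = np.log1p(-p_u)
                a = loglam_u + self._m_ndays * l1p
                b = -lam_u + self._m_total * (np.log(p_u) - l1p) + self._m_lognorm
            else:
                a = loglam_u - self._m_ndays * p_u
                b = -lam_u + self._m_total * np.log(p_u) + self._m_lognorm
        U = self._n_units_total
        ll_u = np.empty(U)
        d_ll_u = np.empty(U)
        d_p_u = np.empty(U)
        _scan(self._m_C0, a, b, lam_u, self._m_total, self._m_ndays, p_u,
              binom, ll_u, d_ll_u, d_p_u)
        logp += float(ll_u.sum())

        # ---- chain rule into abundance blocks ----
        grad[lay["b0"]] = np.bincount(self._m_sp, weights=d_ll_u, minlength=S)
        if b1 is not None:
            grad[lay["b1"]] = np.bincount(
                self._m_sp, weights=d_ll_u * self._m_tstd, minlength=S
            )
        B = np.bincount(self._m_spT, weights=d_ll_u, minlength=S * T).reshape(S, T)
        d_xp_lik = np.bincount(
            self._m_spT, weights=d_p_u * p_u * (1.0 - p_u), minlength=S * T
        ).reshape(S, T)
        if spec.center_g:
            # centred: G rows ~ MVN(0, K), K = sd_g^2 * (Rmat(ls_g) + jitter I)
            Rmat = np.exp(-self._year_d2 / (2.0 * ls_g**2))
            Rj = Rmat + 1e-10 * np.eye(T)
            A = np.linalg.solve(Rj, G.T).T          # (S, T) = G K^-1 * sd^2
            Kinv_G = A / sd_g**2
            _, logdet_R = np.linalg.slogdet(Rj)
            logp += float(
                -0.5 * (G * Kinv_G).sum()
                - 0.5 * S * (2 * T * np.log(sd_g) + logdet_R)
            )
            grad[lay["g"]] = (B - Kinv_G).ravel()
            grad[lay["log_sd_g"]] = float((G * Kinv_G).sum() - S * T)
            dR = Rmat * self._year_d2 / ls_g**3
            tr_term = float(np.trace(np.linalg.solve(Rj, dR)))
            quad = sd_g**2 * float(np.einsum("st,tu,su->", Kinv_G, dR, Kinv_G))
            grad[lay["log_ls_g"]] = ls_g * (0.5 * quad - 0.5 * S * tr_term)
        else:
            grad[lay["z_g"]] = (sd_g * (B @ L_g)).ravel()
            grad[lay["log_sd_g"]] = float((G * B).sum())
            grad[lay["log_ls_g"]] = float(
                sd_g * ls_g * ((Z_g @ dL_g.T) * B).sum()
            )

        if spec.spatial:
            C = np.bincount(self._m_spR, weights=d_ll_u, minlength=S * R).reshape(S, R)
            CP = C @ self.basis.phi  # (S, M)
            grad[lay["w_sp"]] = (sd_sp[:, None] * CP * Q[None, :]).ravel()
            grad[lay["log_sd_sp"]] = (C * SP).sum(axis=1)
            dQ = self.basis.sqrt_spd_dlog_ls(ls_sp)
            grad[lay["log_ls_sp"]] = float(
                (sd_sp[:, None] * CP * W * dQ[None, :]).sum()
            )

        # ---- detection-rate prior: p_st ~ Beta(p_t tau, (1-p_t) tau),
        # expressed on the logit scale ----
        alpha = p_t * tau          # (T,)
        beta = (1.0 - p_t) * tau
        lp = log_expit(xp)         # log p_st
        lq = log_expit(-xp)        # log(1 - p_st)
        logp += float(
            (alpha[None, :] * lp + beta[None, :] * lq).sum()
            + S * (gammaln(tau) * T - (gammaln(alpha) + gammaln(beta)).sum())
        )
        d_xp = d_xp_lik + alpha[None, :] - tau * p_st   # total d/d logit p_st
        dig_a, dig_b, dig_t = digamma(alpha), digamma(beta), digamma(tau)
        d_alpha = lp.sum(axis=0) - S * (dig_a - dig_t)   # (T,)
        d_beta = lq.sum(axis=0) - S * (dig_b - dig_t)
        d_pt = tau * (d_alpha - d_beta)
        d_f = d_pt * p_t * (1.0 - p_t)
        d_logtau_beta = float((p_t * d_alpha + (1.0 - p_t) * d_beta).sum() * tau)
        if spec.center_p:
            grad[lay["xp"]] = d_xp.ravel()
        else:
            # xp = f + u/sqrt(tau): chain into u, f and tau, plus the
            # transform Jacobian -0.5*S*T*log(tau)
            logp += -0.5 * S * T * np.log(tau)
            grad[lay["u_p"]] = (d_xp / np.sqrt(tau)).ravel()
            d_f = d_f + d_xp.sum(axis=0)
            d_logtau_beta += float(
                -0.5 * (d_xp * (xp - f[None, :])).sum() - 0.5 * S * T
            )

        # ---- community detection curve f (non-centred GP) ----
        grad[lay["z_f"]] = sd_f * (L_f.T @ d_f)
        grad[lay["log_sd_f"]] = float(f @ d_f)
        grad[lay["log_ls_f"]] = float(sd_f * ls_f * ((dL_f @ z_f) @ d_f))

        # ---- priors ----
        # standard-normal GP weights
        for name in (
            ("z_f",)
            + (() if spec.center_g else ("z_g",))
            + (("w_sp",) if spec.spatial else ())
        ):
            z = theta[lay[name]]
            logp += -0.5 * float(z @ z)
            grad[lay[name]] += -z
        # intercepts / slopes
        for name in ("b0",) + (("b1",) if spec.variant == "M2" else ()):
            bb = theta[lay[name]]
            logp += -0.5 * float(bb @ bb) / pr.beta_sd**2
            grad[lay[name]] += -bb / pr.beta_sd**2
        # half-normal marginal SDs (log-scale with Jacobian)
        for name, scale in (
            ("log_sd_f", pr.gp_sd_scale),
            ("log_sd_g", pr.gp_sd_scale),
        ) + ((("log_sd_sp", pr.sp_sd_scale),) if spec.spatial else ()):
            u = theta[lay[name]]
            v = np.exp(u)
            logp += float((-0.5 * v**2 / scale**2 + u).sum())
            grad[lay[name]] += -(v**2) / scale**2 + 1.0
        # log-normal lengthscales
        for name, mu, sig in (
            ("log_ls_f", self.ls_mu, pr.ls_sigma),
            ("log_ls_g", self.ls_mu, pr.ls_sigma),
        ) + (
            (("log_ls_sp", self.sp_ls_mu, pr.sp_ls_sigma),) if self.spec.spatial else ()
        ):
            u = self._get(theta, name)
            logp += float((-0.5 * (u - mu) ** 2 / sig**2).sum())
            grad[self.layout[name]] += -(u - mu) / sig**2
        # half-normal tau (log scale with Jacobian)
        u = self._get(theta, "log_tau")[0]
        logp += -0.5 * tau**2 / pr.tau_scale**2 + u
        grad[self.layout["log_tau"]] += (
            d_logtau_beta - tau**2 / pr.tau_scale**2 + 1.0
        )
        return logp, grad

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_and_grad(theta)[0]

    # -- derived quantities ---------------------------------------------------

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Per-unit marginal log-likelihood (the LOO observation unit)."""
        fw = self._forward(theta)
        parts = []
        for s, sd in enumerate(self.species_data):
            parts.append(
                sd.loglik(
                    fw["log_lam"][s, sd.site_idx, sd.year_idx],
                    fw["p_st"][s, sd.year_idx],
                )
            )
        return np.concatenate(parts)

    def constrain(self, theta: np.ndarray) -> dict[str, np.ndarray | float]:
        """Map an unconstrained draw to interpretable parameters."""
        fw = self._forward(theta)
        out = {
            "p_t": fw["p_t"],
            "p_st": fw["p_st"],
            "tau": fw["tau"],
            "beta0": fw["b0"],
            "f": fw["f"],
            "g": fw["G"],
            "sd_f": fw["sd_f"],
            "ls_f": fw["ls_f"],
            "sd_g": fw["sd_g"],
            "ls_g": fw["ls_g"],
            "lam": np.exp(fw["log_lam"]),
        }
        if fw["b1"] is not None:
            out["beta1"] = fw["b1"]
        if self.spec.spatial:
            out["spatial"] = fw["SP"]
            out["sd_sp"] = fw["sd_sp"]
            out["ls_sp"] = fw["ls_sp"]
        return out

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        """Data-informed jittered starting point."""
        theta = 0.1 * rng.standard_normal(self.dim)
        p0 = 0.3
        b0 = np.empty(self.S)
        for s, sd in enumerate(self.species_data):
            mean_daily = sd.total.sum() / max(sd.n_days.sum(), 1)
            b0[s] = np.log(np.clip(mean_daily / p0, 0.05, None))
        theta[self.layout["b0"]] = b0 + 0.1 * rng.standard_normal(self.S)
        xp0 = np.log(p0 / (1 - p0)) + 0.2 * rng.standard_normal(self.S * self.T)
        if self.spec.center_p:
            theta[self.layout["xp"]] = xp0
        else:
            # u such that logit p_st starts near logit(p0) given f ~ 0, tau = 5
            theta[self.layout["u_p"]] = np.sqrt(5.0) * xp0
        theta[self.layout["log_sd_f"]] = np.log(0.5)
        theta[self.layout["log_sd_g"]] = np.log(0.2)
        theta[self.layout["log_ls_f"]] = self.ls_mu
        theta[self.layout["log_ls_g"]] = self.ls_mu
        theta[self.layout["log_tau"]] = np.log(5.0)
        if self.spec.spatial:
            theta[self.layout["log_sd_sp"]] = np.log(0.3)
            theta[self.layout["log_ls_sp"]] = self.sp_ls_mu
        return theta
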