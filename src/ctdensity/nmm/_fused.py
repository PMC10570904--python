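"""Compiled single-pass evaluation of the N-mixture log-posterior.

Mirrors ``NMixtureModel._logp_and_grad_numpy`` exactly (the tests
compare the two on random points across every model variant); exists
because NUTS spends essentially all its time in this function.
"""

from __future__ import annotations

import math

import numpy as np

try:
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = ["HAVE_FUSED", "fused_logp_grad"]

HAVE_FUSED = _HAVE_NUMBA

if _HAVE_NUMBA:
    from .._gp import _chol_dlength_small
    from .likelihood import _scan_kernel

    @numba.njit(cache=False)
    def _expit(x):
        if x >= 0.0:
            return 1.0 / (1.0 + math.exp(-x))
        e = math.exp(x)
        return e / (1.0 + e)

    @numba.njit(cache=False)
    def _log_expit(x):
        if x >= 0.0:
            return -math.log1p(math.exp(-x))
        return x - math.log1p(math.exp(x))

    @numba.njit(cache=False)
    def _digamma(x):
        # ascending recurrence + asymptotic series (AS 103), x > 0
        r = 0.0
        while x < 6.0:
            r -= 1.0 / x
            x += 1.0
        f = 1.0 / (x * x)
        return (
            r
            + math.log(x)
            - 0.5 / x
            - f
            * (
                1.0 / 12.0
                - f
                * (
                    1.0 / 120.0
                    - f * (1.0 / 252.0 - f * (1.0 / 240.0 - f * (1.0 / 132.0)))
                )
            )
        )

    @numba.njit(cache=False)
    def _fused(
        theta,
        offs,        # int64[:]: block offsets, see model.py
        flags,       # int64[:]: m2, spatial, center_p, center_g, binom
        priors,      # float64[:]: beta_sd, gp_sd, ls_mu, ls_sig, tau_sc,
                     #             sp_sd, sp_ls_mu, sp_ls_sig, jitter
        dims,        # int64[:]: S, R, T, M
        year_d2, t_std,
        C0, m_sp, m_site, m_year, m_spT, m_spR,
        m_total, m_ndays, m_lognorm, m_tstd,
        phi, omega2,
        grad,        # out: float64[:]
    ):
        S, R, T, M = dims[0], dims[1], dims[2], dims[3]
        m2 = flags[0] == 1
        spatial = flags[1] == 1
        center_p = flags[2] == 1
        center_g = flags[3] == 1
        binom = flags[4] == 1
        (o_zf, o_sdf, o_lsf, o_tau, o_xp, o_b0, o_b1, o_g, o_sdg, o_lsg,
         o_w, o_sdsp, o_lssp) = (
            offs[0], offs[1], offs[2], offs[3], offs[4], offs[5], offs[6],
            offs[7], offs[8], offs[9], offs[10], offs[11], offs[12],
        )
        grad[:] = 0.0
        logp = 0.0

        sd_f = math.exp(theta[o_sdf])
        ls_f = math.exp(theta[o_lsf])
        sd_g = math.exp(theta[o_sdg])
        ls_g = math.exp(theta[o_lsg])
        tau = math.exp(theta[o_tau])
        sqrt_tau = math.sqrt(tau)
        z_f = theta[o_zf : o_zf + T]
        b0 = theta[o_b0 : o_b0 + S]

        if not (np.isfinite(tau) and tau > 0.0 and np.isfinite(sd_f)
                and np.isfinite(ls_f) and np.isfinite(sd_g) and np.isfinite(ls_g)):
            return -np.inf

        L_f, dL_f = _chol_dlength_small(year_d2, ls_f, priors[8])
        f = sd_f * np.dot(L_f, z_f)
        p_t = np.empty(T)
        for t in range(T):
            p_t[t] = _expit(f[t])
            # community rate saturated to a float boundary: impossible state
            # under the beta prior (digamma/lgamma poles) — reject
            if p_t[t] <= 0.0 or p_t[t] >= 1.0:
                return -np.inf

        xp = np.empty((S, T))
        if center_p:
            for s in range(S):
                for t in range(T):
                    xp[s, t] = theta[o_xp + s * T + t]
        else:
            for s in range(S):
                for t in range(T):
                    xp[s, t] = f[t] + theta[o_xp + s * T + t] / sqrt_tau
        p_st = np.empty((S, T))
        for s in range(S):
            for t in range(T):
                p_st[s, t] = _expit(xp[s, t])

        G = np.empty((S, T))
        if center_g:
            for s in range(S):
                for t in range(T):
                    G[s, t] = theta[o_g + s * T + t]
            L_g = np.zeros((1, 1))
            dL_g = np.zeros((1, 1))
        else:
            L_g, dL_g = _chol_dlength_small(year_d2, ls_g, priors[8])
            for s in range(S):
                for t in range(T):
                    acc = 0.0
                    for k in range(T):
                        acc += L_g[t, k] * theta[o_g + s * T + k]
                    G[s, t] = sd_g * acc

        U = m_sp.size
        if spatial:
            sd_sp = np.empty(S)
            for s in range(S):
                sd_sp[s] = math.exp(theta[o_sdsp + s])
            ls_sp = math.exp(theta[o_lssp])
            Q = np.empty(M)
            for m in range(M):
                Q[m] = (
                    math.sqrt(2.0 * math.pi)
                    * ls_sp
                    * math.exp(-(ls_sp * ls_sp) * omega2[m] / 4.0)
                )
            W = np.empty((S, M))
            for s in range(S):
                for m in range(M):
                    W[s, m] = theta[o_w + s * M + m]
            SP = np.empty((S, R))
            for s in range(S):
                for i in range(R):
                    acc = 0.0
                    for m in range(M):
                        acc += W[s, m] * Q[m] * phi[i, m]
                    SP[s, i] = sd_sp[s] * acc
        else:
            sd_sp = np.zeros(1)
            ls_sp = 0.0
            Q = np.zeros(1)
            W = np.zeros((1, 1))
            SP = np.zeros((1, 1))

        # per-unit predictors
        loglam_u = np.empty(U)
        p_u = np.empty(U)
        lam_u = np.empty(U)
        a = np.empty(U)
        bshift = np.empty(U)
        for u in range(U):
            s = m_sp[u]
            t = m_year[u]
            ll = b0[s] + G[s, t]
            if m2:
                ll += theta[o_b1 + s] * m_tstd[u]
            if spatial:
                ll += SP[s, m_site[u]]
            loglam_u[u] = ll
            lam_u[u] = math.exp(ll)
            pu = p_st[s, t]
            p_u[u] = pu
            if binom:
                if pu < 1.0 and pu > 0.0:
                    l1p = math.log1p(-pu)
                    a[u] = ll + m_ndays[u] * l1p
                    bshift[u] = (
                        -lam_u[u] + m_total[u] * (math.log(pu) - l1p) + m_lognorm[u]
                    )
                else:
                    a[u] = ll
                    bshift[u] = -np.inf
            else:
                a[u] = ll - m_ndays[u] * pu
                if pu > 0.0:
                    bshift[u] = -lam_u[u] + m_total[u] * math.log(pu) + m_lognorm[u]
                else:
                    bshift[u] = -np.inf

        ll_u = np.empty(U)
        d_ll_u = np.empty(U)
        d_p_u = np.empty(U)
        _scan_kernel(C0, a, bshift, lam_u, m_total, m_ndays, p_u, binom,
                     ll_u, d_ll_u, d_p_u)
        for u in range(U):
            logp += ll_u[u]

        # scatter-accumulate likelihood gradients
        B = np.zeros((S, T))
        d_xp = np.zeros((S, T))
        C = np.zeros((S, R))
        for u in range(U):
            s = m_sp[u]
            t = m_year[u]
            g_ = d_ll_u[u]
            grad[o_b0 + s] += g_
            if m2:
                grad[o_b1 + s] += g_ * m_tstd[u]
            B[s, t] += g_
            pu = p_u[u]
            d_xp[s, t] += d_p_u[u] * pu * (1.0 - pu)
            if spatial:
                C[s, m_site[u]] += g_

        # abundance GP curves
        if center_g:
            Rmat = np.empty((T, T))
            for i in range(T):
                for j in range(T):
                    Rmat[i, j] = math.exp(-year_d2[i, j] / (2.0 * ls_g * ls_g))
            Rj = Rmat + 1e-10 * np.eye(T)
            Rinv = np.linalg.inv(Rj)
            KinvG = np.dot(G, Rinv) / (sd_g * sd_g)   # (S, T)
            logdet = math.log(np.linalg.det(Rj))
            acc = 0.0
            for s in range(S):
                for t in range(T):
                    acc += G[s, t] * KinvG[s, t]
            logp += -0.5 * acc - 0.5 * S * (2.0 * T * math.log(sd_g) + logdet)
            for s in range(S):
                for t in range(T):
                    grad[o_g + s * T + t] = B[s, t] - KinvG[s, t]
            grad[o_sdg] += acc - S * T
            dR = Rmat * year_d2 / (ls_g * ls_g * ls_g)
            tr = 0.0
            RinvdR = np.dot(Rinv, dR)
            for t in range(T):
                tr += RinvdR[t, t]
            quad = 0.0
            for s in range(S):
                for i in range(T):
                    for j in range(T):
                        quad += KinvG[s, i] * dR[i, j] * KinvG[s, j]
            quad *= sd_g * sd_g
            grad[o_lsg] += ls_g * (0.5 * quad - 0.5 * S * tr)
        else:
            acc_sd = 0.0
            acc_ls = 0.0
            for s in range(S):
                for t in range(T):
                    accz = 0.0
                    for k in range(T):
                        accz += B[s, k] * L_g[k, t]
                    grad[o_g + s * T + t] = sd_g * accz
                    acc_sd += G[s, t] * B[s, t]
                    accd = 0.0
                    for k in range(T):
                        accd += dL_g[t, k] * theta[o_g + s * T + k]
                    acc_ls += accd * B[s, t]
            grad[o_sdg] += acc_sd
            grad[o_lsg] += sd_g * ls_g * acc_ls

        if spatial:
            CP = np.dot(C, phi)  # (S, M)
            acc_ls = 0.0
            for s in range(S):
                acc_sd = 0.0
                for m in range(M):
                    grad[o_w + s * M + m] = sd_sp[s] * CP[s, m] * Q[m]
                    dQ = Q[m] * (1.0 - (ls_sp * ls_sp) * omega2[m] / 2.0)
                    acc_ls += sd_sp[s] * CP[s, m] * W[s, m] * dQ
                for i in range(R):
                    acc_sd += C[s, i] * SP[s, i]
                grad[o_sdsp + s] += acc_sd
            grad[o_lssp] += acc_ls

        # beta prior on detection rates (logit scale)
        dig_tau = _digamma(tau)
        lg_tau = math.lgamma(tau)
        d_f = np.zeros(T)
        d_logtau = 0.0
        for t in range(T):
            alpha = p_t[t] * tau
            beta = (1.0 - p_t[t]) * tau
            dig_a = _digamma(alpha)
            dig_b = _digamma(beta)
            logp += S * (lg_tau - math.lgamma(alpha) - math.lgamma(beta))
            d_alpha = -S * (dig_a - dig_tau)
            d_beta = -S * (dig_b - dig_tau)
            for s in range(S):
                lp_ = _log_expit(xp[s, t])
                lq_ = _log_expit(-xp[s, t])
                logp += alpha * lp_ + beta * lq_
                d_alpha += lp_
                d_beta += lq_
                dx = d_xp[s, t] + alpha - tau * p_st[s, t]
                d_xp[s, t] = dx
            d_f[t] += tau * (d_alpha - d_beta) * p_t[t] * (1.0 - p_t[t])
            d_logtau += (p_t[t] * d_alpha + (1.0 - p_t[t]) * d_beta) * tau

        if center_p:
            for s in range(S):
                for t in range(T):
                    grad[o_xp + s * T + t] += d_xp[s, t]
        else:
            logp += -0.5 * S * T * math.log(tau)
            d_logtau += -0.5 * S * T
            for s in range(S):
                for t in range(T):
                    grad[o_xp + s * T + t] += d_xp[s, t] / sqrt_tau
                    d_f[t] += d_xp[s, t]
                    d_logtau += -0.5 * d_xp[s, t] * (xp[s, t] - f[t])

        # community curve f (non-centred)
        acc_sd = 0.0
        acc_ls = 0.0
        for t in range(T):
            accz = 0.0
            accd = 0.0
            for k in range(T):
                accz += L_f[k, t] * d_f[k]
                accd += dL_f[t, k] * z_f[k]
            grad[o_zf + t] += sd_f * accz
            acc_sd += f[t] * d_f[t]
            acc_ls += accd * d_f[t]
        grad[o_sdf] += acc_sd
        grad[o_lsf] += sd_f * ls_f * acc_ls

        # ---- priors ----
        beta_sd2 = priors[0] * priors[0]
        for t in range(T):
            z = theta[o_zf + t]
            logp += -0.5 * z * z
            grad[o_zf + t] += -z
        if not center_g:
            for k in range(S * T):
                z = theta[o_g + k]
                logp += -0.5 * z * z
                grad[o_g + k] += -z
        if spatial:
            for k in range(S * M):
                z = theta[o_w + k]
                logp += -0.5 * z * z
                grad[o_w + k] += -z
            # half-normal spatial SDs
            for s in range(S):
                v = math.exp(theta[o_sdsp + s])
                logp += -0.5 * v * v / (priors[5] * priors[5]) + theta[o_sdsp + s]
                grad[o_sdsp + s] += -(v * v) / (priors[5] * priors[5]) + 1.0
            u_ = theta[o_lssp]
            logp += -0.5 * (u_ - priors[6]) ** 2 / (priors[7] * priors[7])
            grad[o_lssp] += -(u_ - priors[6]) / (priors[7] * priors[7])
        for s in range(S):
            bb = theta[o_b0 + s]
            logp += -0.5 * bb * bb / beta_sd2
            grad[o_b0 + s] += -bb / beta_sd2
            if m2:
                bb = theta[o_b1 + s]
                logp += -0.5 * bb * bb / beta_sd2
                grad[o_b1 + s] += -bb / beta_sd2
        gp_sd2 = priors[1] * priors[1]
        for off in (o_sdf, o_sdg):
            v = math.exp(theta[off])
            logp += -0.5 * v * v / gp_sd2 + theta[off]
            grad[off] += -(v * v) / gp_sd2 + 1.0
        ls_sig2 = priors[3] * priors[3]
        for off in (o_lsf, o_lsg):
            u_ = theta[off]
            logp += -0.5 * (u_ - priors[2]) ** 2 / ls_sig2
            grad[off] += -(u_ - priors[2]) / ls_sig2
        # half-normal tau
        tau_sc2 = priors[4] * priors[4]
        logp += -0.5 * tau * tau / tau_sc2 + theta[o_tau]
        grad[o_tau] += d_logtau - tau * tau / tau_sc2 + 1.0

        return logp


def fused_logp_grad(model, theta: np.ndarray) -> tuple[float, np.ndarray]:
    """Evaluate via the compiled kernel using the model's cached arrays."""
    grad = np.empty_like(theta)
    logp = _fused(theta, *model._fused_args, grad)
    return float(logp), grad
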