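"""Marginalized N-mixture observation likelihood.

The latent abundance N of one site-year is summed out up to a finite
bound K::

    log p(y_1..J | lambda, p) =
        log sum_{N=0}^{K} Poisson(N; lambda) * prod_j f(y_j | N, p)

with ``f`` either Poisson(y; N p) — a trapping *rate*, tolerant of
double counts — or Binomial(y; N, p).  All sums run in log space.

:func:`log_marginal_obs` is the scalar reference form.
:class:`SpeciesCounts` is the vectorized form used by the model: for the
Poisson family the day product depends on the data only through the
daily total and the number of active days, which collapses each
site-year to three sufficient statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp  # noqa: F401  (logsumexp: reference form)

try:  # compiled inner loop; the numpy path below is the reference
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = ["log_marginal_obs", "SpeciesCounts", "scan_units"]


if _HAVE_NUMBA:

    @numba.njit
    def _scan_kernel(C0, a, b, lam, total, n_days, p, family_binom,
                     out_ll, out_dlam, out_dp):
        """Online log-sum-exp over the latent grid with early stopping.

        The log-mass is concave in N (Poisson/binomial day terms plus a
        Poisson latent prior are all concave), so once the running term
        has passed its peak and fallen 45 log-units below the maximum,
        the remaining tail is numerically zero.
        """
        U, K1 = C0.shape
        for u in range(U):
            pu = p[u]
            if pu <= 0.0 or (family_binom and pu >= 1.0):
                # underflowed detection rate: reject the state
                out_ll[u] = -np.inf
                out_dlam[u] = 0.0
                out_dp[u] = 0.0
                continue
            au = a[u]
            mx = -np.inf
            s = 0.0
            sn = 0.0
            prev = -np.inf
            for k in range(K1):
                m = C0[u, k] + au * k
                if m != m or m == -np.inf:  # NaN or impossible state
                    prev = -np.inf
                    continue
                if m > mx:
                    if mx > -np.inf:
                        scale = np.exp(mx - m)
                        s *= scale
                        sn *= scale
                    mx = m
                    w = 1.0
                else:
                    d = m - mx
                    if d < -45.0 and m < prev:
                        break
                    w = np.exp(d)
                s += w
                sn += w * k
                prev = m
            if s == 0.0 or not np.isfinite(mx):
                # numerically impossible state (divergent trajectory):
                # reject via -inf log-density
                out_ll[u] = -np.inf
                out_dlam[u] = 0.0
                out_dp[u] = 0.0
                continue
            EN = sn / s
            out_ll[u] = mx + np.log(s) + b[u]
            out_dlam[u] = EN - lam[u]
            if family_binom:
                out_dp[u] = total[u] / p[u] - (n_days[u] * EN - total[u]) / (1.0 - p[u])
            else:
                out_dp[u] = total[u] / p[u] - n_days[u] * EN


def scan_units(C0, a, b, lam, total, n_days, p, family_binom,
               out_ll, out_dlam, out_dp) -> None:
    """Marginal log-likelihood + gradients for a batch of units.

    ``C0`` is the constant (U, K+1) block; the remaining per-unit vectors
    define the N-linear and constant parts (see SpeciesCounts).  Uses the
    compiled early-terminating scan when available, otherwise a full-grid
    numpy evaluation.
    """
    if _HAVE_NUMBA:
        _scan_kernel(C0, a, b, lam, total, n_days, p, family_binom,
                     out_ll, out_dlam, out_dp)
        return
    N = np.arange(C0.shape[1], dtype=float)
    bad = (p <= 0.0) | (family_binom & (p >= 1.0)) | ~np.isfinite(a)
    a_safe = np.where(bad, 0.0, a)
    M = C0 + np.multiply.outer(a_safe, N)
    mx = M.max(axis=1)
    with np.errstate(invalid="ignore"):
        W = np.exp(M - mx[:, None])
    tot = W.sum(axis=1)
    EN = (W @ N) / tot
    out_ll[:] = np.where(bad, -np.inf, mx + np.log(tot) + b)
    out_dlam[:] = np.where(bad, 0.0, EN - lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        if family_binom:
            dp = total / p - (n_days * EN - total) / (1.0 - p)
        else:
            dp = total / p - n_days * EN
    out_dp[:] = np.where(bad, 0.0, dp)


def log_marginal_obs(y_vec, lam: float, p: float, K: int, family: str = "poisson") -> float:
    """Marginal log-probability of one site-year's daily counts.

    Parameters
    ----------
    y_vec
        Counts over the J active days.
    lam
        Expected latent abundance (> 0; the limit lam -> 0 with all-zero
        counts tends to log-probability 0).
    p
        Detection rate per individual per day (Poisson family) or
        detection probability (binomial family).
    K
        Truncation bound of the latent sum; must be >= max(y) for the
        binomial family.
    """
    y = np.asarray(y_vec, dtype=np.int64)
    if family not in ("poisson", "binomial"):
        raise ValueError(f"unknown family {family!r}")
    if family == "binomial" and K < y.max(initial=0):
        raise ValueError("K must be >= max(y) under the binomial family")
    N = np.arange(K + 1)
    log_prior = N * np.log(lam) - lam - gammaln(N + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if family == "poisson":
            mu = N[:, None] * p  # (K+1, J)
            log_f = y[None, :] * np.log(mu) - mu - gammaln(y + 1)[None, :]
            # N = 0: pmf is 1 at y = 0, 0 otherwise
            log_f[0] = np.where(y == 0, 0.0, -np.inf)
        else:
            log_f = (
                gammaln(N + 1)[:, None]
                - gammaln(y + 1)[None, :]
                - gammaln(N[:, None] - y[None, :] + 1)
                + y[None, :] * np.log(p)
                + (N[:, None] - y[None, :]) * np.log1p(-p)
            )
            log_f = np.where(N[:, None] >= y[None, :], log_f, -np.inf)
    return float(logsumexp(log_prior + log_f.sum(axis=1)))


@dataclass
class SpeciesCounts:
    """Precomputed per-species count data for fast repeated evaluation.

    One observation unit is a site-year with at least one active survey
    day.  Ordering of units is (site-major, year-minor) and is shared by
    the pointwise log-likelihood used for LOO.
    """

    site_idx: np.ndarray   # (U,)
    year_idx: np.ndarray   # (U,)
    n_days: np.ndarray     # (U,) active days J_u
    total: np.ndarray      # (U,) sum of daily counts
    K: int
    family: str
    log_norm: np.ndarray   # (U,) -sum_j log y_j! (Poisson) etc.
    binom_coef: np.ndarray | None  # (U, K+1) sum_j log C(N, y_j), -inf if N < max y
    # cached grids
    _N: np.ndarray = None
    _logN: np.ndarray = None
    _lgN1: np.ndarray = None

    @classmethod
    def from_arrays(
        cls, y: np.ndarray, effort: np.ndarray, K: int | None = None,
        family: str = "poisson",
    ) -> "SpeciesCounts":
        """Build from one species' (R, J, T) counts and the effort mask."""
        R, J, T = y.shape
        if K is None:
            K = int(y.max(initial=0)) + 100
        units = [(i, t) for i in range(R) for t in range(T) if effort[i, :, t].any()]
        site_idx = np.array([u[0] for u in units], dtype=np.int64)
        year_idx = np.array([u[1] for u in units], dtype=np.int64)
        n_days = np.array([int(effort[i, :, t].sum()) for i, t in units])
        ys = [y[i, effort[i, :, t], t] for i, t in units]
        total = np.array([int(v.sum()) for v in ys])
        # -sum_j log y_j! — for the binomial family this constant already
        # sits inside the binomial coefficients
        if family == "poisson":
            log_norm = np.array([-float(gammaln(v + 1).sum()) for v in ys])
        else:
            log_norm = np.zeros(len(units))
        binom_coef = None
        if family == "binomial":
            if K < y.max(initial=0):
                raise ValueError("K must be >= max(y) under the binomial family")
            N = np.arange(K + 1)
            binom_coef = np.empty((len(units), K + 1))
            for u, v in enumerate(ys):
                with np.errstate(divide="ignore"):
                    c = (
                        gammaln(N + 1)[:, None]
                        - gammaln(v + 1)[None, :]
                        - gammaln(N[:, None] - v[None, :] + 1)
                    )
                c = np.where(N[:, None] >= v[None, :], c, -np.inf)
                binom_coef[u] = c.sum(axis=1)
        N = np.arange(K + 1)
        with np.errstate(divide="ignore"):
            logN = np.log(N.astype(float))
        return cls(
            site_idx=site_idx, year_idx=year_idx, n_days=n_days, total=total,
            K=K, family=family, log_norm=log_norm, binom_coef=binom_coef,
            _N=N.astype(float), _logN=logN, _lgN1=gammaln(N + 1),
        )

    @property
    def n_units(self) -> int:
        return self.site_idx.size

    # The joint log-mass over the latent grid separates into a constant
    # (U, K+1) block plus a term linear in N plus a per-unit shift:
    #   M[u, N] = C0[u, N] + a_u * N + b_u
    # with, for the Poisson family,
    #   a_u = log lam_u - J_u p_u,  b_u = -lam_u + T_u log p_u + log_norm_u
    # and for the binomial family
    #   a_u = log lam_u + J_u log(1-p_u),
    #   b_u = -lam_u + T_u (log p_u - log(1-p_u)) + log_norm_u.
    # Only the cheap rank-one part is rebuilt per evaluation.

    def _const_block(self) -> np.ndarray:
        if getattr(self, "_C0", None) is None:
            if self.family == "poisson":
                with np.errstate(invalid="ignore"):
                    C0 = self.total[:, None] * self._logN[None, :] - self._lgN1[None, :]
                C0[self.total == 0, 0] = 0.0  # 0 * log 0 at an all-zero unit
            else:
                C0 = self.binom_coef - self._lgN1[None, :]
            self._C0 = C0
        return self._C0

    def _ab(self, log_lam: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lam = np.exp(log_lam)
        if self.family == "poisson":
            a = log_lam - self.n_days * p
            b = -lam + self.total * np.log(p) + self.log_norm
        else:
            l1p = np.log1p(-p)
            a = log_lam + self.n_days * l1p
            b = -lam + self.total * (np.log(p) - l1p) + self.log_norm
        return a, b

    def loglik(self, log_lam: np.ndarray, p: np.ndarray) -> np.ndarray:
        """Pointwise marginal log-likelihood per unit: (U,)."""
        return self.loglik_grad(log_lam, p)[0]

    def loglik_grad(
        self, log_lam: np.ndarray, p: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(pointwise loglik, d/dlog_lam, d/dp) — all (U,)."""
        if _HAVE_NUMBA:
            a, b = self._ab(log_lam, p)
            U = a.size
            ll = np.empty(U)
            d_loglam = np.empty(U)
            d_p = np.empty(U)
            _scan_kernel(
                self._const_block(), a, b, np.exp(log_lam),
                self._total_f, self._n_days_f, p,
                self.family == "binomial", ll, d_loglam, d_p,
            )
            return ll, d_loglam, d_p
        return self._loglik_grad_numpy(log_lam, p)

    def _loglik_grad_numpy(
        self, log_lam: np.ndarray, p: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pure-numpy full-grid evaluation (reference for the kernel)."""
        a, b = self._ab(log_lam, p)
        M = self._const_block() + np.multiply.outer(a, self._N)
        mx = M.max(axis=1)
        np.exp(M - mx[:, None], out=M)
        tot = M.sum(axis=1)
        ll = mx + np.log(tot) + b
        EN = (M @ self._N) / tot
        d_loglam = EN - np.exp(log_lam)
        if self.family == "poisson":
            d_p = self.total / p - self.n_days * EN
        else:
            d_p = self.total / p - (self.n_days * EN - self.total) / (1.0 - p)
        return ll, d_loglam, d_p

    @property
    def _total_f(self) -> np.ndarray:
        if getattr(self, "_total_float", None) is None:
            self._total_float = self.total.astype(np.float64)
            self._n_days_float = self.n_days.astype(np.float64)
        return self._total_float

    @property
    def _n_days_f(self) -> np.ndarray:
        self._total_f  # ensure caches
        return self._n_days_float
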