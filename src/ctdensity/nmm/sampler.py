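"""No-U-Turn sampler with dual-averaging step size and adaptive metric.

A self-contained NUTS implementation (doubling tree with slice
sampling, dynamic termination on the U-turn criterion, divergence
detection) driven by any ``logp_and_grad`` callable.  Warmup follows
the usual three-phase schedule: an initial step-size-only buffer,
doubling metric-adaptation windows, and a terminal step-size buffer.
The metric is the regularized posterior covariance estimate — diagonal
or dense; the dense option matters here because the N-mixture
posterior carries strong abundance-detection ridges that a diagonal
metric cannot absorb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NUTSResult", "nuts_sample"]

_DIVERGENCE = 1000.0  # log-joint error treated as a divergent transition


@dataclass
class NUTSResult:
    draws: np.ndarray          # (n_samples, dim) post-warmup
    logp: np.ndarray           # (n_samples,)
    divergent: np.ndarray      # (n_samples,) bool
    accept_mean: float
    step_size: float
    treedepth_mean: float
    warmup_draws: np.ndarray | None = None  # (n_warmup, dim)
    inv_metric: np.ndarray | None = None    # final metric (vector or matrix)

    @property
    def n_divergent(self) -> int:
        return int(self.divergent.sum())


class _Dual:
    """Nesterov dual averaging of the log step size."""

    def __init__(self, eps0: float, delta: float):
        self.mu = np.log(10.0 * eps0)
        self.delta = delta
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.m = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob: float) -> float:
        self.m += 1
        w = 1.0 / (self.m + self.t0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.delta - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.h_bar
        eta = self.m ** (-self.kappa)
        self.log_eps_bar = eta * self.log_eps + (1.0 - eta) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _Metric:
    """Diagonal or dense kinetic-energy metric (posterior covariance)."""

    def __init__(self, dim: int, dense: bool):
        self.dim = dim
        self.dense = dense
        self.set(np.ones(dim) if not dense else np.eye(dim))

    def set(self, cov) -> None:
        self.cov = cov
        if self.dense:
            self._chol = np.linalg.cholesky(cov)
        else:
            self._sqrt = np.sqrt(cov)

    def update_from(self, X: np.ndarray) -> None:
        """Regularized covariance of warmup draws (Stan-style shrinkage).

        A dense estimate needs several draws per dimension to be usable;
        below that the update falls back to the (shrunk) diagonal.
        """
        n = X.shape[0]
        if n < 10:
            return
        emp_var = X.var(axis=0, ddof=1)
        diag = (n * emp_var + 5.0) / (n + 5.0)
        if self.dense:
            if n >= 3 * self.dim:
                emp = np.cov(X.T)
                cov = (n / (n + 5.0)) * emp + (5.0 / (n + 5.0)) * np.eye(self.dim)
            else:
                cov = np.diag(diag)
            self.set(cov)
        else:
            self.set(diag)

    def velocity(self, r: np.ndarray) -> np.ndarray:
        return self.cov @ r if self.dense else self.cov * r

    def kinetic(self, r: np.ndarray) -> float:
        return 0.5 * float(r @ self.velocity(r))

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.dim)
        if self.dense:
            return np.linalg.solve(self._chol.T, z)
        return z / self._sqrt


def _warmup_windows(n_warmup: int) -> list[int]:
    """Iteration indices at which the metric is re-estimated.

    Doubling windows between an initial step-size-only buffer and a
    terminal step-size buffer; the final window is the longest so the
    last metric estimate rests on the best-mixed draws.
    """
    if n_warmup < 60:
        return []
    init = max(int(0.1 * n_warmup), 10)
    term = max(int(0.12 * n_warmup), 10)
    ends = []
    start, size = init, max(int(0.06 * n_warmup), 25)
    while start + size < n_warmup - term:
        ends.append(start + size)
        start += size
        size *= 2
    ends.append(n_warmup - term)
    return ends


def nuts_sample(
    logp_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    theta0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    seed: int | np.random.Generator,
    target_accept: float = 0.85,
    max_treedepth: int = 10,
    dense_metric: bool = False,
    init_inv_metric: np.ndarray | None = None,
    adapt_metric: bool = True,
) -> NUTSResult:
    """Run one NUTS chain; returns post-warmup draws and diagnostics.

    ``init_inv_metric`` seeds the kinetic metric (posterior covariance;
    a vector for diagonal, a matrix for dense); with ``adapt_metric``
    False the warmup only tunes the step size against that fixed metric
    — the mode used when several chains share one adaptation phase.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = np.array(theta0, dtype=float)
    dim = theta.size
    metric = _Metric(dim, dense_metric)
    if init_inv_metric is not None:
        metric.dense = init_inv_metric.ndim == 2
        metric.set(init_inv_metric)

    logp, grad = logp_and_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log-density")

    def leapfrog(th, r, gr, eps):
        r1 = r + 0.5 * eps * gr
        th1 = th + eps * metric.velocity(r1)
        lp1, gr1 = logp_and_grad(th1)
        r1 = r1 + 0.5 * eps * gr1
        return th1, r1, lp1, gr1

    def _find_eps() -> float:
        eps = 0.1
        r = metric.sample_momentum(rng)
        joint0 = logp - metric.kinetic(r)
        _, r1, lp1, _ = leapfrog(theta, r, grad, eps)
        dj = (lp1 - metric.kinetic(r1)) - joint0 if np.isfinite(lp1) else -np.inf
        direction = 1.0 if dj > np.log(0.5) else -1.0
        for _ in range(50):
            eps *= 2.0**direction
            _, r1, lp1, _ = leapfrog(theta, r, grad, eps)
            dj = (lp1 - metric.kinetic(r1)) - joint0 if np.isfinite(lp1) else -np.inf
            if direction * dj < direction * np.log(0.5):
                break
        return eps

    # recursive doubling (Hoffman & Gelman alg. 6)
    def build_tree(th, r, gr, lp, logu, v, j, eps, joint0):
        if j == 0:
            th1, r1, lp1, gr1 = leapfrog(th, r, gr, v * eps)
            joint = (lp1 - metric.kinetic(r1)) if np.isfinite(lp1) else -np.inf
            n1 = int(logu <= joint)
            diverged = (joint - joint0) < -_DIVERGENCE or not np.isfinite(joint)
            alpha = min(1.0, np.exp(min(joint - joint0, 0.0)))
            return (th1, r1, gr1, lp1, th1, r1, gr1, lp1, th1, lp1,
                    n1, not diverged, alpha, 1, diverged)
        (thm, rm, grm, lpm, thp, rp, grp, lpp, th1, lp1,
         n1, s1, a1, na1, div1) = build_tree(th, r, gr, lp, logu, v, j - 1, eps, joint0)
        diverged = div1
        if s1:
            if v == -1:
                (thm, rm, grm, lpm, _, _, _, _, th2, lp2,
                 n2, s2, a2, na2, div2) = build_tree(
                    thm, rm, grm, lpm, logu, v, j - 1, eps, joint0)
            else:
                (_, _, _, _, thp, rp, grp, lpp, th2, lp2,
                 n2, s2, a2, na2, div2) = build_tree(
                    thp, rp, grp, lpp, logu, v, j - 1, eps, joint0)
            if n1 + n2 > 0 and rng.random() < n2 / (n1 + n2):
                th1, lp1 = th2, lp2
            a1, na1 = a1 + a2, na1 + na2
            dth = thp - thm
            s1 = (
                s2
                and (dth @ metric.velocity(rm)) >= 0.0
                and (dth @ metric.velocity(rp)) >= 0.0
            )
            n1 += n2
            diverged = diverged or div2
        return (thm, rm, grm, lpm, thp, rp, grp, lpp, th1, lp1,
                n1, s1, a1, na1, diverged)

    eps = _find_eps()
    dual = _Dual(eps, target_accept)
    windows = _warmup_windows(n_warmup) if adapt_metric else []
    win_buf: list[np.ndarray] = []
    warm_draws: list[np.ndarray] = []

    draws = np.empty((n_samples, dim))
    logps = np.empty(n_samples)
    div_flags = np.zeros(n_samples, dtype=bool)
    accepts: list[float] = []
    depths: list[int] = []

    total = n_warmup + n_samples
    for it in range(total):
        warm = it < n_warmup
        r0 = metric.sample_momentum(rng)
        joint0 = logp - metric.kinetic(r0)
        logu = joint0 + np.log(rng.random())
        thm = thp = theta
        rm = rp = r0
        grm = grp = grad
        lpm = lpp = logp
        n, s, j = 1, True, 0
        alpha_sum, n_alpha = 0.0, 0
        diverged = False
        while s and j < max_treedepth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                (thm, rm, grm, lpm, _, _, _, _, th1, lp1,
                 n1, s1, a1, na1, div) = build_tree(
                    thm, rm, grm, lpm, logu, v, j, eps, joint0)
            else:
                (_, _, _, _, thp, rp, grp, lpp, th1, lp1,
                 n1, s1, a1, na1, div) = build_tree(
                    thp, rp, grp, lpp, logu, v, j, eps, joint0)
            if s1 and rng.random() < min(1.0, n1 / n):
                theta, logp = th1, lp1
                _, grad = logp_and_grad(theta)
            n += n1
            alpha_sum += a1
            n_alpha += na1
            diverged = diverged or div
            dth = thp - thm
            s = (
                s1
                and (dth @ metric.velocity(rm)) >= 0.0
                and (dth @ metric.velocity(rp)) >= 0.0
            )
            j += 1
        accept = alpha_sum / max(n_alpha, 1)

        if warm:
            eps = dual.update(accept)
            win_buf.append(theta.copy())
            warm_draws.append(theta)
            if it + 1 in windows:
                metric.update_from(np.asarray(win_buf))
                win_buf = []
                eps = _find_eps()
                dual = _Dual(eps, target_accept)
        else:
            draws[it - n_warmup] = theta
            logps[it - n_warmup] = logp
            div_flags[it - n_warmup] = diverged
            accepts.append(accept)
            depths.append(j)
        if it == n_warmup - 1:
            eps = dual.adapted()

    return NUTSResult(
        draws=draws,
        logp=logps,
        divergent=div_flags,
        accept_mean=float(np.mean(accepts)) if accepts else float("nan"),
        step_size=eps,
        treedepth_mean=float(np.mean(depths)) if depths else float("nan"),
        warmup_draws=np.asarray(warm_draws) if warm_draws else None,
        inv_metric=metric.cov,
    )
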