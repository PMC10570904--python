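"""Squared-exponential GP kernel helpers shared by the simulator and models."""

from __future__ import annotations

import numpy as np

try:
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

JITTER = 1e-10


def sqexp_corr(x: np.ndarray, lengthscale: float) -> np.ndarray:
    """Unit-variance squared-exponential correlation matrix on points ``x``.

    ``x`` may be 1-D (n,) or 2-D (n, d); isotropic in d dimensions.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.size > 1:
        x = x.T
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * lengthscale**2))


def sqexp_kernel(x: np.ndarray, marginal_sd: float, lengthscale: float) -> np.ndarray:
    return marginal_sd**2 * sqexp_corr(x, lengthscale)


def chol_corr(x: np.ndarray, lengthscale: float) -> np.ndarray:
    """Cholesky factor of the correlation matrix (jittered for stability)."""
    R = sqexp_corr(x, lengthscale)
    return np.linalg.cholesky(R + JITTER * np.eye(R.shape[0]))


def chol_corr_dlength(x: np.ndarray, lengthscale: float) -> tuple[np.ndarray, np.ndarray]:
    """Cholesky factor L of the correlation and its derivative dL/d(lengthscale)."""
    x2 = np.atleast_2d(np.asarray(x, dtype=float))
    if x2.shape[0] == 1 and x2.size > 1:
        x2 = x2.T
    d2 = np.sum((x2[:, None, :] - x2[None, :, :]) ** 2, axis=-1)
    return chol_corr_dlength_from_d2(d2, lengthscale)


def _chol_dlength_numpy(d2: np.ndarray, lengthscale: float) -> tuple[np.ndarray, np.ndarray]:
    R = np.exp(-d2 / (2.0 * lengthscale**2))
    R.flat[:: R.shape[0] + 1] += JITTER
    L = np.linalg.cholesky(R)
    dR = R * d2 / lengthscale**3
    A = np.linalg.solve(L, dR)
    A = np.linalg.solve(L, A.T).T  # L^-1 dR L^-T
    Phi = np.tril(A)
    np.fill_diagonal(Phi, 0.5 * np.diag(A))
    return L, L @ Phi


if _HAVE_NUMBA:

    @numba.njit
    def _chol_dlength_small(d2, lengthscale, jitter):
        n = d2.shape[0]
        R = np.exp(-d2 / (2.0 * lengthscale * lengthscale))
        for i in range(n):
            R[i, i] += jitter
        L = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1):
                s = R[i, j]
                for k in range(j):
                    s -= L[i, k] * L[j, k]
                if i == j:
                    L[i, i] = np.sqrt(s)
                else:
                    L[i, j] = s / L[j, j]
        dR = R * d2 / lengthscale**3
        # A = L^-1 dR L^-T by two triangular solves
        A = np.empty((n, n))
        for col in range(n):
            for i in range(n):
                s = dR[i, col]
                for k in range(i):
                    s -= L[i, k] * A[k, col]
                A[i, col] = s / L[i, i]
        B = np.empty((n, n))
        for row in range(n):
            for j in range(n):
                s = A[row, j]
                for k in range(j):
                    s -= B[row, k] * L[j, k]
                B[row, j] = s / L[j, j]
        Phi = np.zeros((n, n))
        for i in range(n):
            for j in range(i):
                Phi[i, j] = B[i, j]
            Phi[i, i] = 0.5 * B[i, i]
        return L, L @ Phi


def chol_corr_dlength_from_d2(
    d2: np.ndarray, lengthscale: float
) -> tuple[np.ndarray, np.ndarray]:
    """As :func:`chol_corr_dlength` given the squared-distance matrix.

    Uses dL = L * Phi(L^-1 dR L^-T) with Phi the lower-triangular-half
    operator (strict lower triangle plus half the diagonal).
    """
    if _HAVE_NUMBA and d2.shape[0] <= 16:
        return _chol_dlength_small(d2, lengthscale, JITTER)
    return _chol_dlength_numpy(d2.copy(), lengthscale)
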