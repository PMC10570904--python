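"""Hilbert-space reduced-rank approximation of a 2-D squared-exponential GP.

The field is expanded in Laplacian eigenfunctions of the rectangle
[-L1, L1] x [-L2, L2] (the data rectangle inflated by a boundary factor
c).  With m basis functions per dimension the field at sites X is

    f(X) = Phi(X) @ (sqrt(S(omega_j; sd, ls)) * z_j),   z_j ~ N(0, 1),

where S is the spectral density of the squared-exponential kernel and
omega_j the eigenfrequencies; the implied covariance converges to the
exact kernel as m and c grow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HSGPBasis", "hsgp_basis"]

_TWO_PI = 2.0 * np.pi


@dataclass
class HSGPBasis:
    """Eigenfunction basis evaluated at the sites, plus spectral helpers."""

    phi: np.ndarray        # (n_sites, m^2)
    omega2: np.ndarray     # (m^2,) squared eigenfrequency norms
    L: np.ndarray          # (2,) boundary half-widths
    center: np.ndarray     # (2,) coordinate centring applied
    m: int
    c: float

    @property
    def n_basis(self) -> int:
        return self.omega2.size

    def sqrt_spd(self, lengthscale: float, marginal_sd: float = 1.0) -> np.ndarray:
        """sqrt of the SE spectral density at the eigenfrequencies (2-D)."""
        # S(w) = sd^2 * 2*pi * ls^2 * exp(-ls^2 |w|^2 / 2)
        return (
            marginal_sd
            * np.sqrt(_TWO_PI)
            * lengthscale
            * np.exp(-(lengthscale**2) * self.omega2 / 4.0)
        )

    def sqrt_spd_dlog_ls(self, lengthscale: float, marginal_sd: float = 1.0) -> np.ndarray:
        """d sqrt_spd / d log(lengthscale)."""
        q = self.sqrt_spd(lengthscale, marginal_sd)
        return q * (1.0 - (lengthscale**2) * self.omega2 / 2.0)

    def implied_cov(self, lengthscale: float, marginal_sd: float = 1.0) -> np.ndarray:
        """Approximate covariance matrix at the sites."""
        spd = self.sqrt_spd(lengthscale, marginal_sd) ** 2
        return (self.phi * spd[None, :]) @ self.phi.T


def hsgp_basis(
    site_coords: np.ndarray,
    m: int = 20,
    c: float = 1.5,
    half_widths: np.ndarray | None = None,
) -> HSGPBasis:
    """Build the reduced-rank basis at the site centroids.

    Coordinates are centred internally; ``half_widths`` (per dimension,
    before inflation by ``c``) default to the data half-ranges.
    """
    if m < 2:
        raise ValueError("need at least 2 basis functions per dimension")
    if c < 1.2:
        raise ValueError("boundary factor c must be >= 1.2")
    X = np.asarray(site_coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("site_coords must be (n_sites, 2)")
    center = X.mean(axis=0)
    Xc = X - center
    if half_widths is None:
        half_widths = np.abs(Xc).max(axis=0)
    half_widths = np.maximum(np.asarray(half_widths, dtype=float), 1e-9)
    L = c * half_widths

    j = np.arange(1, m + 1)
    # per-dimension eigenfrequencies and eigenfunctions
    om = [np.pi * j / (2.0 * L[d]) for d in range(2)]
    phi_d = [
        np.sin(om[d][None, :] * (Xc[:, d : d + 1] + L[d])) / np.sqrt(L[d])
        for d in range(2)
    ]
    # tensor products over the two dimensions
    phi = (phi_d[0][:, :, None] * phi_d[1][:, None, :]).reshape(X.shape[0], m * m)
    omega2 = (om[0][:, None] ** 2 + om[1][None, :] ** 2).reshape(m * m)
    return HSGPBasis(phi=phi, omega2=omega2, L=L, center=center, m=m, c=c)
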