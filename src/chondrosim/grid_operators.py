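"""Radial and age discretizations.

Space: a uniform cell-centered grid on the disk radius [0, r_max] under
circular symmetry.  The diffusion operator is a flux-form (finite-volume)
discretization of ``(1/r) d/dr (r D du/dr)`` with zero-flux conditions at
the center (coordinate symmetry) and at the outer edge (closed explant).
Centering the unknowns between edges keeps the scheme second order for
smooth fields and sidesteps the 1/r singularity at the origin.

Age (time since signaling): a uniform finite-volume grid of ``n_a`` bins
on [0, a_cap], unknowns at bin centers, with first-order upwind transport
at unit speed in flux form.  The flux form makes the discrete age mass
balance exact — the change of total mass over a step equals (inflow at
age zero minus outflow past ``a_cap``) times dt — and the update becomes
an exact one-bin shift when dt equals the age spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "RadialGrid",
    "AgeGrid",
    "make_radial_grid",
    "make_age_grid",
    "radial_diffusion_matrix",
    "diffusion_bands",
    "age_advection_step",
]


@dataclass
class RadialGrid:
    n_r: int
    dr: float
    centers: np.ndarray  # cell-center radii, cm; strictly positive
    edges: np.ndarray    # cell-edge radii, edges[0] = 0, edges[-1] = r_max
    cell_areas: np.ndarray  # exact annular areas pi (e_{i+1}^2 - e_i^2), cm^2

    @property
    def r_max(self) -> float:
        return float(self.edges[-1])


@dataclass
class AgeGrid:
    n_a: int
    da: float
    centers: np.ndarray  # bin-center ages, days
    edges: np.ndarray    # bin edges, edges[0] = 0, edges[-1] = a_cap

    @property
    def a_cap(self) -> float:
        return float(self.edges[-1])

    # midpoint quadrature weights, cached because they sit in the hot loop
    _weights: np.ndarray | None = field(default=None, repr=False)

    @property
    def quad_weights(self) -> np.ndarray:
        if self._weights is None:
            self._weights = np.full(self.n_a, self.da)
        return self._weights


def make_radial_grid(n_r: int, r_max: float) -> RadialGrid:
    if n_r < 1 or r_max <= 0:
        raise ValueError("make_radial_grid: need n_r >= 1 and r_max > 0")
    dr = r_max / n_r
    edges = np.linspace(0.0, r_max, n_r + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    cell_areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    return RadialGrid(n_r=n_r, dr=dr, centers=centers, edges=edges,
                      cell_areas=cell_areas)


def make_age_grid(n_a: int, a_cap: float) -> AgeGrid:
    if n_a < 1 or a_cap <= 0:
        raise ValueError("make_age_grid: need n_a >= 1 and a_cap > 0")
    edges = np.linspace(0.0, a_cap, n_a + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AgeGrid(n_a=n_a, da=a_cap / n_a, centers=centers, edges=edges)


def diffusion_bands(grid: RadialGrid, D: float):
    """Sub-, main- and super-diagonal of the radial diffusion operator.

    Row i of the operator reads
    ``(1/(r_i dr)) [ r_{e,i+1} D (u_{i+1}-u_i)/dr - r_{e,i} D (u_i-u_{i-1})/dr ]``
    with zero flux through the first and last edges.  Rows sum to zero
    (constants are annihilated) and area-weighted columns sum to zero
    (total mass is conserved).
    """
    if D < 0:
        raise ValueError("diffusion_bands: diffusivity must be nonnegative")
    r_c = grid.centers
    r_e = grid.edges
    dr = grid.dr
    upper = D * r_e[1:-1] / (r_c[:-1] * dr * dr)   # coupling to cell i+1
    lower = D * r_e[1:-1] / (r_c[1:] * dr * dr)    # coupling to cell i-1
    diag = np.zeros(grid.n_r)
    diag[:-1] -= upper
    diag[1:] -= lower
    return lower, diag, upper


def radial_diffusion_matrix(grid: RadialGrid, D: float) -> sp.csr_matrix:
    """Sparse matrix form of the flux-form radial diffusion operator."""
    lower, diag, upper = diffusion_bands(grid, D)
    return sp.diags(
        [lower, diag, upper], offsets=[-1, 0, 1], format="csr"
    )


def age_advection_step(density_of_a: np.ndarray, da: float, dt: float,
                       inflow_at_zero) -> np.ndarray:
    """First-order upwind transport of an age density toward larger age.

    ``density_of_a`` has age (bin centers) on the last axis;
    ``inflow_at_zero`` is the boundary density entering through the age-0
    edge, cells/(cm^2 day).  Requires ``dt <= da``; at equality the
    update is an exact one-bin shift.  The discrete mass balance is
    exact: ``da * sum`` changes by ``dt * (inflow - last_bin_density)``.
    """
    if dt > da * (1.0 + 1e-12):
        raise ValueError(
            f"age_advection_step: dt={dt!r} exceeds the age spacing "
            f"da={da!r}; the controller must shrink the step"
        )
    nu = dt / da
    out = np.empty_like(density_of_a)
    out[..., 1:] = density_of_a[..., 1:] - nu * (
        density_of_a[..., 1:] - density_of_a[..., :-1]
    )
    out[..., 0] = density_of_a[..., 0] + nu * (
        inflow_at_zero - density_of_a[..., 0]
    )
    return out
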