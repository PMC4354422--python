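"""Reaction and transition terms of the cartilage-lesion model.

Every function here is pure and operates pointwise in space: inputs are
either scalars or arrays whose leading axis is the radial index and (for
the age-structured compartments) whose trailing axis is the age-node
index.  Nothing in this module knows about diffusion or time stepping.

Sign conventions: rates are written so that each transition appears once
as a sink (proportional to the compartment it leaves) and once as a
source or age-boundary inflow at its destination, which is what makes the
discrete cell-count bookkeeping exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ModelParams

__all__ = [
    "ChemState",
    "CellStateLocal",
    "CellRates",
    "heaviside",
    "hill",
    "gamma_kernel",
    "age_integral",
    "chem_reaction_rates",
    "chem_production_rates",
    "ecm_rate",
    "cell_rates",
    "age_boundary_inflows",
]


@dataclass
class ChemState:
    """Chemical concentrations (nanomolar) and ECM density at one or more
    spatial locations."""

    R: np.ndarray | float
    M: np.ndarray | float
    F: np.ndarray | float
    P: np.ndarray | float
    U: np.ndarray | float


@dataclass
class CellStateLocal:
    """Cell densities at one or more spatial locations.

    ``C_T_of_a`` and ``S_T_of_a`` are densities per unit age on the age
    grid (trailing axis); the other fields are plain densities.
    """

    C_U: np.ndarray | float
    C_E: np.ndarray | float
    S_A: np.ndarray | float
    D_N: np.ndarray | float
    C_T_of_a: np.ndarray
    S_T_of_a: np.ndarray


@dataclass
class CellRates:
    """Right-hand sides and bookkeeping fluxes for the cell compartments.

    ``sink_CT`` / ``sink_ST`` are the age-local removal *rates* (1/day,
    multiplying the local age density).  All ``flux_*`` entries are
    cells/(cm^2 day): paired source/sink magnitudes of each transition,
    already integrated over age where applicable.
    """

    dC_U: np.ndarray | float
    dC_E: np.ndarray | float
    dS_A: np.ndarray | float
    dD_N: np.ndarray | float
    sink_CT: np.ndarray
    sink_ST: np.ndarray
    flux_cu_to_ct: np.ndarray | float
    flux_ct_to_st: np.ndarray | float
    flux_ct_to_ce: np.ndarray | float
    flux_st_to_sa: np.ndarray | float
    flux_st_to_da: np.ndarray | float
    flux_sa_to_da: np.ndarray | float
    flux_sa_to_cu: np.ndarray | float
    flux_ce_to_cu: np.ndarray | float
    flux_dn_cleared: np.ndarray | float
    # age integrals of the structured compartments (handy downstream)
    ct_total: np.ndarray | float = 0.0
    st_total: np.ndarray | float = 0.0


def heaviside(theta):
    """Unit step: 1 where ``theta > 0``, else 0.

    The value at exactly 0 is 0 by convention; the baseline trajectory
    never sits exactly on a gate threshold, so any fixed convention gives
    identical dynamics.
    """
    return np.where(np.asarray(theta) > 0, 1.0, 0.0)


def hill(x, lam):
    """Saturating response ``x / (lam + x)``, in [0, 1) for x >= 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill: concentration must be nonnegative")
    if not np.all(np.asarray(lam) > 0):
        raise ValueError("hill: half-saturation constant must be positive")
    return x / (lam + x)


def _hill(x, lam):
    # validation-free variant for the solver hot path (states there are
    # already guaranteed nonnegative)
    return x / (lam + x)


def gamma_kernel(a, a_max, gamma_0, sigma_spread):
    """Smoothed transition-age kernel, 1/day.

    ``(gamma_0 / sigma_spread) * (tanh((a - a_max)/sigma_spread) + 1)``:
    essentially zero for ages well below ``a_max``, rising over a window
    of width ``sigma_spread`` to a plateau ``2 gamma_0 / sigma_spread``.
    As ``sigma_spread -> 0`` the transition concentrates at ``a_max``.
    """
    if not sigma_spread > 0:
        raise ValueError("gamma_kernel: sigma_spread must be positive")
    a = np.asarray(a, dtype=float)
    return (gamma_0 / sigma_spread) * (
        np.tanh((a - a_max) / sigma_spread) + 1.0
    )


def age_integral(density_of_a, ages, weight_of_a=None):
    """Composite-midpoint integral of an age density sampled at uniform
    bin centers.

    Exact for integrands linear in age.  ``density_of_a`` may carry
    leading spatial axes; integration is over the last axis.  The bin
    width is inferred from the (uniform) spacing of ``ages``.
    """
    density_of_a = np.asarray(density_of_a, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if density_of_a.shape[-1] != ages.shape[0]:
        raise ValueError(
            f"age_integral: density has {density_of_a.shape[-1]} age bins "
            f"but the grid has {ages.shape[0]}"
        )
    if ages.shape[0] < 2:
        raise ValueError("age_integral: need at least two age bins")
    da = ages[1] - ages[0]
    if weight_of_a is not None:
        return density_of_a @ (np.asarray(weight_of_a, dtype=float) * da)
    return density_of_a.sum(axis=-1) * da


def chem_production_rates(chem: ChemState, cells: CellStateLocal,
                          p: ModelParams, ages, st_total=None):
    """Source terms of the four chemicals (decay and diffusion excluded).

    ROS and IL-6 are produced by catabolic cells, DAMPs by necrotic cells
    and by cytokine-driven ECM breakdown, and EPO by the EPO-producing
    healthy cells under ROS drive and IL-6 suppression.  ``st_total`` may
    pass in a precomputed age integral of the catabolic density.
    """
    if st_total is None:
        st_total = age_integral(cells.S_T_of_a, ages)
    prod_R = p.sigma_R * st_total
    prod_M = p.sigma_M * cells.D_N + p.delta_U * chem.U * _hill(chem.F, p.lambda_F)
    prod_F = p.sigma_F * st_total
    prod_P = (
        p.sigma_P
        * cells.C_E
        * _hill(chem.R, p.lambda_R)
        * p.Lambda / (p.Lambda + chem.F)
    )
    return prod_R, prod_M, prod_F, prod_P


def chem_reaction_rates(chem: ChemState, cells: CellStateLocal,
                        p: ModelParams, ages):
    """Full non-diffusive rates (production minus natural decay) of
    R, M, F, P in nanomolar/day."""
    prod_R, prod_M, prod_F, prod_P = chem_production_rates(
        chem, cells, p, ages
    )
    dR = -p.delta_R * chem.R + prod_R
    dM = -p.delta_M * chem.M + prod_M
    dF = -p.delta_F * chem.F + prod_F
    dP = -p.delta_P * chem.P + prod_P
    return dR, dM, dF, dP


def ecm_rate(chem: ChemState, p: ModelParams):
    """ECM degradation rate, model-units/day; always <= 0.

    Matrix is degraded by IL-6 with saturation, and the degradation is
    switched off entirely once EPO exceeds its threshold ``P_c``.
    """
    return (
        -p.delta_U
        * chem.U
        * hill(chem.F, p.lambda_F)
        * heaviside(p.P_c - chem.P)
    )


def age_boundary_inflows(chem: ChemState, cells: CellStateLocal,
                         p: ModelParams, ages):
    """Inflow densities at age zero for the two age-structured compartments,
    cells/(cm^2 day).

    Newly ROS-signaled healthy cells enter ``C_T`` at age 0; pre-catabolic
    cells signaled by DAMPs or IL-6 (gated off above the EPO threshold)
    enter ``S_T`` at age 0, drawn from the whole ``C_T`` age distribution
    so that the inflow exactly balances the corresponding age-local sinks.
    """
    inflow_ct = p.beta_13 * cells.C_U * hill(chem.R, p.lambda_R)
    ct_total = age_integral(cells.C_T_of_a, ages)
    inflow_st = (
        (p.beta_11 * hill(chem.M, p.lambda_M)
         + p.beta_12 * hill(chem.F, p.lambda_F))
        * heaviside(p.P_c - chem.P)
        * ct_total
    )
    return inflow_ct, inflow_st


def cell_rates(chem: ChemState, cells: CellStateLocal,
               p: ModelParams, ages) -> CellRates:
    """All cell-compartment rates plus paired bookkeeping fluxes.

    Transitions:
      C_U -> C_T (ROS signaling; boundary inflow, see
      :func:`age_boundary_inflows`), C_T -> S_T (DAMPs/IL-6, EPO-gated),
      C_T -> C_E (delayed, kernel at ``tau_2``, ROS-modulated),
      S_T -> S_A (delayed, kernel at ``tau_1``, IL-6-modulated),
      S_T -> apoptosis (IL-6 and DAMPs), S_A -> apoptosis (IL-6),
      S_A -> C_U (EPO rescue), C_E -> C_U (above-threshold EPO reversion),
      D_N -> cleared (first-order clearance).
    """
    ages = np.asarray(ages, dtype=float)
    h_R = _hill(np.asarray(chem.R, dtype=float), p.lambda_R)
    h_M = _hill(np.asarray(chem.M, dtype=float), p.lambda_M)
    h_F = _hill(np.asarray(chem.F, dtype=float), p.lambda_F)
    h_P = _hill(np.asarray(chem.P, dtype=float), p.lambda_P)
    gate_lo = heaviside(p.P_c - chem.P)   # 1 while EPO below threshold
    gate_hi = heaviside(chem.P - p.P_c)   # 1 once EPO exceeds threshold

    ker_ce = p.kappa_2 * gamma_kernel(ages, p.tau_2,
                                      p.gamma_0, p.sigma_spread)
    ker_sa = p.kappa_1 * gamma_kernel(ages, p.tau_1,
                                      p.gamma_0, p.sigma_spread)

    # scalar-per-location coefficients; broadcast over the age axis
    coef_ct_st = (p.beta_11 * h_M + p.beta_12 * h_F) * gate_lo
    coef_st_da = p.mu_ST * h_F * h_M

    sink_CT = coef_ct_st[..., None] + h_R[..., None] * ker_ce
    sink_ST = coef_st_da[..., None] + h_F[..., None] * ker_sa

    da = ages[1] - ages[0]
    w = np.full(ages.shape[0], da)
    ct_total = cells.C_T_of_a @ w
    st_total = cells.S_T_of_a @ w

    flux_ct_to_st = coef_ct_st * ct_total
    flux_ct_to_ce = h_R * (cells.C_T_of_a @ (ker_ce * da))
    flux_st_to_da = coef_st_da * st_total
    flux_st_to_sa = h_F * (cells.S_T_of_a @ (ker_sa * da))
    flux_sa_to_cu = p.alpha_1 * cells.S_A * h_P
    flux_sa_to_da = p.mu_SA * h_F * cells.S_A
    flux_ce_to_cu = p.alpha_2 * gate_hi * cells.C_E
    flux_dn_cleared = p.mu_DN * cells.D_N
    flux_cu_to_ct = p.beta_13 * cells.C_U * h_R

    dC_U = flux_sa_to_cu + flux_ce_to_cu - flux_cu_to_ct
    dC_E = flux_ct_to_ce - flux_ce_to_cu
    dS_A = flux_st_to_sa - flux_sa_to_cu - flux_sa_to_da
    dD_N = -flux_dn_cleared

    return CellRates(
        dC_U=dC_U,
        dC_E=dC_E,
        dS_A=dS_A,
        dD_N=dD_N,
        sink_CT=sink_CT,
        sink_ST=sink_ST,
        flux_cu_to_ct=flux_cu_to_ct,
        flux_ct_to_st=flux_ct_to_st,
        flux_ct_to_ce=flux_ct_to_ce,
        flux_st_to_sa=flux_st_to_sa,
        flux_st_to_da=flux_st_to_da,
        flux_sa_to_da=flux_sa_to_da,
        flux_sa_to_cu=flux_sa_to_cu,
        flux_ce_to_cu=flux_ce_to_cu,
        flux_dn_cleared=flux_dn_cleared,
        ct_total=ct_total,
        st_total=st_total,
    )
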