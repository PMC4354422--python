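"""Time integration of the full lesion model.

One step is an IMEX splitting, applied in a fixed order so that runs are
bit-reproducible:

1. explicit (forward-Euler) evaluation of every reaction and transition
   term from :mod:`chondrosim.kinetics`;
2. first-order upwind transport of the two age-structured compartments
   with their age-zero boundary inflows;
3. implicit (backward-Euler) solve of diffusion plus natural decay for
   each chemical, as a tridiagonal system per species.

The ECM field has no diffusion term and is updated explicitly.  The time
step is controlled by step doubling: one full step is compared against
two half steps in a per-field relative max-norm, and the half-step
solution is accepted when the estimate meets the tolerance.

Cell-count bookkeeping is exact by construction: every transition sink
has a matching source (or age-boundary inflow) using the same discrete
quadrature, apoptotic and cleared cells go to explicit accumulators, and
cells aging past the truncation age ``a_cap`` accumulate in
``aged_out_accum`` (the flux-form age update makes this outflow exact).
The sum of all compartments plus accumulators therefore stays at the
initial density at every radius, up to round-off and any negativity
clipping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from scipy.linalg import lapack as _lapack

from . import kinetics
from .grid_operators import (
    AgeGrid,
    RadialGrid,
    age_advection_step,
    diffusion_bands,
    make_age_grid,
    make_radial_grid,
)
from .kinetics import CellStateLocal, ChemState
from .parameters import DomainConfig, ModelParams, NumericsConfig, validate

__all__ = [
    "Grids",
    "SimState",
    "Trajectory",
    "make_grids",
    "initial_state",
    "step",
    "adapt_step",
    "simulate",
    "tracked_outputs",
    "snapshot_to_frame",
    "age_resolved_frame",
    "TRACKED_NAMES",
]

# Output names used throughout reports and diagnostics; the two
# age-structured compartments are reported as their age-integrated totals.
TRACKED_NAMES = (
    "C_U", "C_T", "C_E", "S_T", "S_A", "U", "F", "P", "M", "R",
)


@dataclass
class Grids:
    radial: RadialGrid
    age: AgeGrid


def make_grids(dom: DomainConfig, num: NumericsConfig) -> Grids:
    return Grids(
        radial=make_radial_grid(num.n_r, dom.r_max),
        age=make_age_grid(num.n_a, num.a_cap),
    )


@dataclass
class SimState:
    """Full discretized model state at one instant."""

    t: float
    # cell compartments, cells/cm^2 (C_T, S_T are per-age densities)
    C_U: np.ndarray
    C_E: np.ndarray
    S_A: np.ndarray
    D_N: np.ndarray
    C_T: np.ndarray  # shape (n_r, n_a), age-bin densities
    S_T: np.ndarray  # shape (n_r, n_a), age-bin densities
    # chemicals, nanomolar; ECM in model units
    R: np.ndarray
    M: np.ndarray
    F: np.ndarray
    P: np.ndarray
    U: np.ndarray
    # bookkeeping accumulators, cells/cm^2
    D_A_accum: np.ndarray
    N_cleared_accum: np.ndarray
    aged_out_accum: np.ndarray

    def copy(self) -> "SimState":
        return SimState(
            t=self.t,
            **{
                name: getattr(self, name).copy()
                for name in _ARRAY_FIELDS
            },
        )


_ARRAY_FIELDS = (
    "C_U", "C_E", "S_A", "D_N", "C_T", "S_T",
    "R", "M", "F", "P", "U",
    "D_A_accum", "N_cleared_accum", "aged_out_accum",
)

# fields entering the local-error norm
_ERROR_FIELDS = (
    "C_U", "C_E", "S_A", "D_N", "C_T", "S_T", "R", "M", "F", "P", "U",
)


def _error_floors(p: ModelParams, dom: DomainConfig) -> dict[str, float]:
    """Scale floors for the relative error norm: a small fraction of each
    field's characteristic magnitude, so that fields which are still
    essentially empty (e.g. a compartment just being seeded through its
    age boundary) are controlled on an absolute scale instead of blowing
    up the relative estimate."""
    n0 = dom.cell_density_0
    frac = 1e-3
    char = {
        "C_U": n0, "C_E": n0, "S_A": n0, "D_N": n0,
        # age densities carry units cells/(cm^2 day); inflow magnitudes
        # are of order beta_13 * n0
        "C_T": n0, "S_T": n0,
        "R": p.sigma_R * n0,
        "M": p.sigma_M * n0 / p.delta_M,
        "F": p.sigma_F * n0 / p.delta_F,
        "P": p.sigma_P * n0 / p.delta_P,
        "U": dom.U_0,
    }
    return {k: frac * v for k, v in char.items()}


@dataclass
class Trajectory:
    snapshots: list[SimState]
    diagnostics: dict[str, Any]


class _Workspace:
    """Per-run cached quantities: diffusion bands, quadrature weights."""

    def __init__(self, p: ModelParams, grids: Grids,
                 dom: DomainConfig | None = None) -> None:
        self.err_floors = _error_floors(p, dom if dom is not None
                                        else DomainConfig())
        self.bands = {
            "R": (diffusion_bands(grids.radial, p.D_R), p.delta_R),
            "M": (diffusion_bands(grids.radial, p.D_M), p.delta_M),
            "F": (diffusion_bands(grids.radial, p.D_F), p.delta_F),
            "P": (diffusion_bands(grids.radial, p.D_P), p.delta_P),
        }
        self.w_age = grids.age.quad_weights


def initial_state(dom: DomainConfig, p: ModelParams, grids: Grids) -> SimState:
    """Post-impact initial condition.

    Cells whose center lies inside the impact radius are fully necrotic;
    everything outside is healthy at the nominal density.  ROS carries the
    burst released by dying cells (``sigma_R`` per necrotic cell); all
    other chemicals start at zero and the ECM at its nominal density.
    """
    r = grids.radial.centers
    inside = r < dom.r_impact
    n_r = grids.radial.n_r
    n_a = grids.age.n_a
    zeros = np.zeros(n_r)
    D_N = np.where(inside, dom.cell_density_0, 0.0)
    return SimState(
        t=0.0,
        C_U=np.where(inside, 0.0, dom.cell_density_0),
        C_E=zeros.copy(),
        S_A=zeros.copy(),
        D_N=D_N,
        C_T=np.zeros((n_r, n_a)),
        S_T=np.zeros((n_r, n_a)),
        R=p.sigma_R * D_N,
        M=zeros.copy(),
        F=zeros.copy(),
        P=zeros.copy(),
        U=np.full(n_r, dom.U_0),
        D_A_accum=zeros.copy(),
        N_cleared_accum=zeros.copy(),
        aged_out_accum=zeros.copy(),
    )


def _eval_rates(state: SimState, p: ModelParams, grids: Grids):
    """All explicit reaction/production rates at the given state."""
    chem = ChemState(R=state.R, M=state.M, F=state.F, P=state.P, U=state.U)
    cells = CellStateLocal(
        C_U=state.C_U, C_E=state.C_E, S_A=state.S_A, D_N=state.D_N,
        C_T_of_a=state.C_T, S_T_of_a=state.S_T,
    )
    cr = kinetics.cell_rates(chem, cells, p, grids.age.centers)
    prods = kinetics.chem_production_rates(
        chem, cells, p, grids.age.centers, st_total=cr.st_total
    )
    dU = kinetics.ecm_rate(chem, p)
    return cr, prods, dU


def step(state: SimState, dt: float, p: ModelParams, grids: Grids,
         ws: _Workspace | None = None, rates=None) -> SimState:
    """Advance the state by one IMEX step of size ``dt`` (days).

    Raises if ``dt`` exceeds the age spacing (the upwind age transport is
    run at unit CFL or below).  ``rates`` may pass in the explicit rates
    already evaluated at ``state`` (they depend only on the state, so the
    step-doubling controller shares them between trial steps).
    """
    ag = grids.age
    if dt > ag.da * (1.0 + 1e-12):
        raise ValueError(
            f"step: dt={dt!r} violates the age CFL limit da={ag.da!r}"
        )
    if ws is None:
        ws = _Workspace(p, grids)
    if rates is None:
        rates = _eval_rates(state, p, grids)
    cr, (prod_R, prod_M, prod_F, prod_P), dU = rates

    # (i) explicit reactions: unstructured cell compartments + accumulators
    C_U = state.C_U + dt * cr.dC_U
    C_E = state.C_E + dt * cr.dC_E
    S_A = state.S_A + dt * cr.dS_A
    D_N = state.D_N + dt * cr.dD_N
    D_A = state.D_A_accum + dt * (cr.flux_st_to_da + cr.flux_sa_to_da)
    N_cl = state.N_cleared_accum + dt * cr.flux_dn_cleared

    # (ii) age-structured compartments: explicit sinks, then upwind aging
    # in flux form with the age-zero boundary inflows.  The outflow
    # through the a_cap edge is exactly dt times the last-bin density, so
    # the aged-out accumulator pairs exactly with the advection update.
    C_T_star = state.C_T - dt * (cr.sink_CT * state.C_T)
    S_T_star = state.S_T - dt * (cr.sink_ST * state.S_T)
    C_T = age_advection_step(C_T_star, ag.da, dt, cr.flux_cu_to_ct)
    S_T = age_advection_step(S_T_star, ag.da, dt, cr.flux_ct_to_st)
    aged = state.aged_out_accum + dt * (C_T_star[:, -1] + S_T_star[:, -1])

    # (iii) implicit decay + diffusion per chemical (backward Euler);
    # the tridiagonal systems (I + dt (delta I - L)) u_new = u + dt prod
    # are M-matrices, so nonnegative inputs stay nonnegative
    new_chem = {}
    for name, prod in (("R", prod_R), ("M", prod_M),
                       ("F", prod_F), ("P", prod_P)):
        (lower, diag, upper), delta = ws.bands[name]
        rhs = getattr(state, name) + dt * prod
        _, _, _, x, info = _lapack.dgtsv(
            -dt * lower, 1.0 + dt * delta - dt * diag, -dt * upper, rhs,
            1, 1, 1, 1,
        )
        if info != 0:
            raise RuntimeError(
                f"step: tridiagonal solve for {name} failed (info={info})"
            )
        new_chem[name] = x

    # ECM: no diffusion, explicit update
    U = state.U + dt * dU

    return SimState(
        t=state.t + dt,
        C_U=C_U, C_E=C_E, S_A=S_A, D_N=D_N, C_T=C_T, S_T=S_T,
        R=new_chem["R"], M=new_chem["M"], F=new_chem["F"], P=new_chem["P"],
        U=U,
        D_A_accum=D_A, N_cleared_accum=N_cl, aged_out_accum=aged,
    )


def _error_norm(y1: SimState, y2: SimState,
                floors: dict[str, float]) -> float:
    """Relative max-norm distance between two states, maximized over
    fields; each field is scaled by its own magnitude (with a floor)."""
    worst = 0.0
    for name in _ERROR_FIELDS:
        a = getattr(y1, name)
        b = getattr(y2, name)
        scale = max(float(np.max(np.abs(b))), floors[name])
        err = float(np.max(np.abs(a - b))) / scale
        if err > worst:
            worst = err
    return worst


def _clip_negative(state: SimState, threshold: float = 1e-6) -> int:
    """Clip negative entries to zero in place; return the number of
    entries that were below ``-threshold`` (significant clips)."""
    n_sig = 0
    for name in _ARRAY_FIELDS:
        arr = getattr(state, name)
        neg = arr < 0.0
        if neg.any():
            n_sig += int(np.count_nonzero(arr < -threshold))
            np.clip(arr, 0.0, None, out=arr)
    return n_sig


def adapt_step(state: SimState, dt_try: float, tol: float,
               p: ModelParams, grids: Grids,
               ws: _Workspace | None = None,
               dt_min: float = 1e-9,
               dt_max: float = np.inf) -> tuple[SimState, float, float]:
    """One accepted step under step-doubling local-error control.

    Compares one step of ``dt`` against two steps of ``dt/2``; accepts the
    half-step solution when the relative max-norm estimate is within
    ``tol``, otherwise halves and retries.  Returns the accepted state,
    the step actually used, and a suggestion for the next step (grown by
    at most a factor of two).
    """
    if ws is None:
        ws = _Workspace(p, grids)
    dt = min(dt_try, dt_max, grids.age.da)
    rates0 = _eval_rates(state, p, grids)
    while True:
        y1 = step(state, dt, p, grids, ws, rates=rates0)
        y_half = step(state, 0.5 * dt, p, grids, ws, rates=rates0)
        y2 = step(y_half, 0.5 * dt, p, grids, ws)
        err = _error_norm(y1, y2, ws.err_floors)
        if err <= tol:
            if err > 0 and np.isfinite(tol):
                factor = min(2.0, max(0.2, 0.9 * np.sqrt(tol / err)))
            else:
                factor = 2.0
            dt_next = float(np.clip(dt * factor, dt_min, dt_max))
            return y2, dt, dt_next
        if dt <= dt_min * (1.0 + 1e-9):
            raise RuntimeError(
                f"adapt_step: error estimate {err:.3e} exceeds tol={tol:.3e} "
                f"at the minimum step dt_min={dt_min:.3e} (t={state.t:.6f})"
            )
        dt = max(0.5 * dt, dt_min)


def tracked_outputs(state: SimState, grids: Grids) -> dict[str, np.ndarray]:
    """Spatial profiles of the ten reported variables (age-structured
    compartments integrated over age)."""
    w = grids.age.quad_weights
    return {
        "C_U": state.C_U,
        "C_T": state.C_T @ w,
        "C_E": state.C_E,
        "S_T": state.S_T @ w,
        "S_A": state.S_A,
        "U": state.U,
        "F": state.F,
        "P": state.P,
        "M": state.M,
        "R": state.R,
    }


def _conservation_residual(state: SimState, grids: Grids,
                           cell_density_0: float) -> float:
    w = grids.age.quad_weights
    total = (
        state.C_U + state.C_T @ w + state.C_E + state.S_T @ w
        + state.S_A + state.D_N
        + state.D_A_accum + state.N_cleared_accum + state.aged_out_accum
    )
    return float(np.max(np.abs(total - cell_density_0)) / cell_density_0)


def simulate(p: ModelParams, dom: DomainConfig,
             num: NumericsConfig) -> Trajectory:
    """Run the model from the post-impact state to ``dom.t_end``.

    Lands exactly on every requested snapshot time.  Diagnostics include
    the running maximum of EPO (and whether the ``P >= P_c`` gate ever
    fired), per-snapshot cell-conservation residuals, the accepted-step
    history, negativity-clip counts, the residual age-density at the
    truncation age, and per-step area-weighted integrals of every tracked
    output (used by the sensitivity study to detect oscillatory onset).
    """
    diags_cfg = validate(p, dom, num)
    if diags_cfg:
        raise ValueError(
            "invalid configuration:\n  " + "\n  ".join(diags_cfg)
        )
    grids = make_grids(dom, num)
    ws = _Workspace(p, grids, dom)
    state = initial_state(dom, p, grids)

    snapshot_times = list(dom.snapshot_times)
    targets = sorted(set(snapshot_times) | {dom.t_end})
    areas = grids.radial.cell_areas

    snapshots: list[SimState] = []
    t_hist: list[float] = []
    dt_hist: list[float] = []
    series: dict[str, list[float]] = {name: [] for name in TRACKED_NAMES}
    conservation: list[float] = []
    max_P = float(np.max(state.P))
    gate_fired = max_P >= p.P_c
    n_clip = 0

    def record(s: SimState) -> None:
        nonlocal max_P, gate_fired
        p_now = float(np.max(s.P))
        if p_now > max_P:
            max_P = p_now
        if p_now >= p.P_c:
            gate_fired = True
        t_hist.append(s.t)
        for name, profile in tracked_outputs(s, grids).items():
            series[name].append(float(areas @ profile))

    record(state)
    if snapshot_times and abs(snapshot_times[0]) < 1e-12:
        snapshots.append(state.copy())
        conservation.append(
            _conservation_residual(state, grids, dom.cell_density_0)
        )
        snapshot_times = snapshot_times[1:]

    dt_cap = min(num.dt_max, grids.age.da)
    dt_next = min(num.dt_init, dt_cap)
    for target in targets:
        if target <= state.t + 1e-12:
            continue
        while state.t < target - 1e-12:
            dt_try = min(dt_next, dt_cap, target - state.t)
            dt_try = max(dt_try, num.dt_min)
            state, dt_used, dt_next = adapt_step(
                state, dt_try, num.tol, p, grids, ws,
                dt_min=num.dt_min, dt_max=dt_cap,
            )
            n_clip += _clip_negative(state)
            dt_hist.append(dt_used)
            record(state)
        state.t = target  # remove float residue from the landing
        while snapshot_times and snapshot_times[0] <= target + 1e-12:
            snapshots.append(state.copy())
            conservation.append(
                _conservation_residual(state, grids, dom.cell_density_0)
            )
            snapshot_times = snapshot_times[1:]

    w = grids.age.quad_weights
    age_cap_residual = max(
        (float(np.max(s.C_T[:, -1] + s.S_T[:, -1]) * grids.age.da)
         for s in snapshots),
        default=0.0,
    )
    diagnostics: dict[str, Any] = {
        "max_P": max_P,
        "gate_fired": gate_fired,
        "n_steps": len(dt_hist),
        "dt_hist": np.asarray(dt_hist),
        "t_hist": np.asarray(t_hist),
        "series": {k: np.asarray(v) for k, v in series.items()},
        "conservation_residuals": conservation,
        "n_significant_clips": n_clip,
        "age_cap_residual": age_cap_residual,
    }
    return Trajectory(snapshots=snapshots, diagnostics=diagnostics)


# --- snapshot output -----------------------------------------------------

def snapshot_to_frame(state: SimState, grids: Grids) -> pd.DataFrame:
    """One row per radial cell: center radius, every spatial field (age
    compartments as totals), and the bookkeeping accumulators."""
    data = {"r_center": grids.radial.centers}
    data.update(tracked_outputs(state, grids))
    data["D_N"] = state.D_N
    data["D_A_accum"] = state.D_A_accum
    data["N_cleared_accum"] = state.N_cleared_accum
    data["aged_out_accum"] = state.aged_out_accum
    return pd.DataFrame(data)


def age_resolved_frame(state: SimState, grids: Grids) -> pd.DataFrame:
    """Long-format age-resolved densities of the two structured
    compartments: columns (r, a, C_T, S_T)."""
    r = np.repeat(grids.radial.centers, grids.age.n_a)
    a = np.tile(grids.age.centers, grids.radial.n_r)
    return pd.DataFrame({
        "r": r,
        "a": a,
        "C_T": state.C_T.ravel(),
        "S_T": state.S_T.ravel(),
    })
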