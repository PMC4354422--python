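"""Computational studies built on the simulator.

Three studies mirror how this class of model is validated and explored:

* a spatial grid-refinement convergence study (relative max-norm errors
  at the final day against a refined reference run);
* a one-at-a-time parameter-sensitivity scan around the baseline,
  summarizing each tracked output by its area-weighted spatial integral
  at the final day and classifying trajectories as monotone or
  oscillatory;
* radial binning of spatial profiles into fixed-width annuli for
  side-by-side comparison with experimentally binned cell counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


import numpy as np
import pandas as pd

from .grid_operators import RadialGrid
from .parameters import DomainConfig, ModelParams, NumericsConfig
from .simulator import (
    TRACKED_NAMES,
    Trajectory,
    make_grids,
    simulate,
    tracked_outputs,
)

__all__ = [
    "ConvergenceReport",
    "SensitivityReport",
    "SensitivityEntry",
    "DEFAULT_PERTURBATIONS",
    "convergence_study",
    "sensitivity_study",
    "radial_binning",
    "day14_summaries",
    "load_binned_counts",
    "overlay_with_simulation",
    "convergence_to_frame",
    "sensitivity_to_frame",
]


# One-at-a-time perturbation plan: parameter -> (perturbed values,
# qualitative-stability interval).  The beta_11 row is kept as is
# even though its stability interval [60, 70] contains none of
# the perturbed values and excludes the base value 100; it is therefore
# excluded from interval-based direction checks downstream.
DEFAULT_PERTURBATIONS: dict[str, tuple[tuple[float, ...], tuple[float, float]]] = {
    "lambda_R": ((1.0, 3.0, 7.0, 9.0), (3.0, 7.0)),
    "lambda_M": ((0.1, 0.3, 0.7, 0.9), (0.3, 0.7)),
    "lambda_F": ((0.1, 0.3, 0.7, 0.9), (0.3, 0.7)),
    "lambda_P": ((0.1, 0.3, 0.7, 0.9), (0.3, 0.9)),
    "alpha_1": ((0.1, 0.5, 1.5, 2.0), (0.5, 2.0)),
    "beta_11": ((50.0, 75.0, 125.0, 150.0), (60.0, 70.0)),
    "beta_12": ((40.0, 45.0, 55.0, 60.0), (40.0, 60.0)),
    "beta_13": ((1.0, 5.0, 15.0, 20.0), (5.0, 15.0)),
    "kappa_1": ((1.0, 5.0, 15.0, 20.0), (5.0, 20.0)),
    "kappa_2": ((1.0, 5.0, 15.0, 20.0), (5.0, 20.0)),
    "mu_ST": ((0.1, 0.3, 0.7, 0.9), (0.1, 0.9)),
    "mu_SA": ((0.01, 0.05, 0.15, 0.2), (0.01, 0.2)),
    "mu_DN": ((0.01, 0.03, 0.07, 0.09), (0.01, 0.09)),
}


@dataclass
class ConvergenceReport:
    """Relative errors of the final-day solution under spatial refinement."""

    interval_counts: list[int]
    errors: dict[str, list[float]]  # variable -> error per count
    reference: str

    def max_error(self, count: int) -> float:
        i = self.interval_counts.index(count)
        return max(errs[i] for errs in self.errors.values())


@dataclass
class SensitivityEntry:
    parameter: str
    base_value: float
    perturbed_values: list[float]
    interval: tuple[float, float]
    # per perturbed value: output -> signed relative change vs baseline
    rel_changes: dict[float, dict[str, float]]
    # aggregate direction over the stability interval per output
    directions: dict[str, str]  # 'decrease' | 'increase' | 'none'
    # per perturbed value: did any output trajectory turn oscillatory?
    qualitative_change: dict[float, bool]


@dataclass
class SensitivityReport:
    entries: list[SensitivityEntry]
    baseline_summaries: dict[str, float]
    threshold: float


def day14_summaries(traj: Trajectory, dom: DomainConfig,
                    num: NumericsConfig) -> dict[str, float]:
    """Area-weighted spatial integral of each tracked output at the last
    snapshot (the final day of the run)."""
    grids = make_grids(dom, num)
    areas = grids.radial.cell_areas
    out = tracked_outputs(traj.snapshots[-1], grids)
    return {name: float(areas @ profile) for name, profile in out.items()}


def convergence_study(
    p: ModelParams,
    dom: DomainConfig,
    num_base: NumericsConfig,
    interval_counts: tuple[int, ...] = (100, 200, 400, 800),
    reference_multiplier: int = 2,
) -> ConvergenceReport:
    """Grid-refinement study of the baseline run.

    Runs the simulation at each spatial resolution (fixed age grid and
    time tolerance) plus a reference at ``reference_multiplier`` times
    the finest count; reports, per tracked variable, the relative
    max-norm difference of the final-day profile against the reference
    linearly interpolated to the coarse cell centers.
    """
    counts = sorted(int(c) for c in interval_counts)
    if counts != list(interval_counts):
        raise ValueError("interval_counts must be sorted ascending")
    if reference_multiplier < 2:
        raise ValueError("reference_multiplier must be at least 2")
    n_ref = counts[-1] * reference_multiplier

    def run(n_r: int):
        num = dataclasses.replace(num_base, n_r=n_r)
        traj = simulate(p, dom, num)
        grids = make_grids(dom, num)
        return grids.radial.centers, tracked_outputs(
            traj.snapshots[-1], grids
        )

    r_ref, out_ref = run(n_ref)
    errors: dict[str, list[float]] = {name: [] for name in TRACKED_NAMES}
    for count in counts:
        r_c, out_c = run(count)
        for name in TRACKED_NAMES:
            ref_interp = np.interp(r_c, r_ref, out_ref[name])
            scale = float(np.max(np.abs(ref_interp)))
            diff = float(np.max(np.abs(out_c[name] - ref_interp)))
            errors[name].append(diff / scale if scale > 0 else 0.0)
    return ConvergenceReport(
        interval_counts=counts,
        errors=errors,
        reference=f"{n_ref} intervals ({reference_multiplier}x finest), "
                  f"linearly interpolated to coarse centers, "
                  f"relative max-norm at t = {dom.t_end} days",
    )


def _is_oscillatory(t: np.ndarray, s: np.ndarray,
                    t_skip: float = 2.0, rel_tol: float = 1e-3) -> bool:
    """Classify a time series as oscillatory: more than one sign change
    of its discrete derivative after the initial transient, counting only
    swings larger than ``rel_tol`` of the series range."""
    mask = t >= t_skip
    if mask.sum() < 3:
        return False
    s = s[mask]
    scale = float(np.max(s) - np.min(s))
    if scale <= 0:
        return False
    # compress to alternating significant moves
    sign = 0
    changes = 0
    anchor = s[0]
    for value in s[1:]:
        move = value - anchor
        if abs(move) < rel_tol * scale:
            continue
        new_sign = 1 if move > 0 else -1
        if sign != 0 and new_sign != sign:
            changes += 1
        sign = new_sign
        anchor = value
    return changes >= 2


def sensitivity_study(
    p: ModelParams,
    dom: DomainConfig,
    num: NumericsConfig,
    plan: dict[str, tuple[tuple[float, ...], tuple[float, float]]] | None = None,
    threshold: float = 0.01,
) -> SensitivityReport:
    """One-at-a-time parameter scan around the baseline.

    For every parameter and perturbed value, reruns the simulation and
    reports the signed relative change of each tracked output's final-day
    area-weighted integral.  The aggregate direction over the stability
    interval is the sign of the summary trend across in-interval values
    (including the base), reported as 'none' when every in-interval
    change stays below ``threshold``.  A per-value flag records whether
    any output trajectory switched from monotone to oscillatory.
    """
    if plan is None:
        plan = DEFAULT_PERTURBATIONS
    base_traj = simulate(p, dom, num)
    base_sum = day14_summaries(base_traj, dom, num)
    base_osc = {
        name: _is_oscillatory(base_traj.diagnostics["t_hist"],
                              base_traj.diagnostics["series"][name])
        for name in TRACKED_NAMES
    }

    entries: list[SensitivityEntry] = []
    for pname, (values, interval) in plan.items():
        base_value = float(getattr(p, pname))
        rel_changes: dict[float, dict[str, float]] = {}
        qual: dict[float, bool] = {}
        in_interval: dict[float, dict[str, float]] = {
            base_value: {name: 0.0 for name in TRACKED_NAMES}
        }
        for value in values:
            pert = dataclasses.replace(p, **{pname: float(value)})
            traj = simulate(pert, dom, num)
            summ = day14_summaries(traj, dom, num)
            changes = {
                name: (summ[name] - base_sum[name])
                / (abs(base_sum[name]) if base_sum[name] != 0 else 1.0)
                for name in TRACKED_NAMES
            }
            rel_changes[float(value)] = changes
            qual[float(value)] = any(
                _is_oscillatory(traj.diagnostics["t_hist"],
                                traj.diagnostics["series"][name])
                and not base_osc[name]
                for name in TRACKED_NAMES
            )
            if interval[0] <= value <= interval[1]:
                in_interval[float(value)] = changes

        directions: dict[str, str] = {}
        xs = sorted(in_interval)
        for name in TRACKED_NAMES:
            ys = [in_interval[x][name] for x in xs]
            span = max(ys) - min(ys)
            if len(xs) < 2 or span < threshold:
                directions[name] = "none"
            else:
                directions[name] = (
                    "increase" if ys[-1] > ys[0] else "decrease"
                )
        entries.append(SensitivityEntry(
            parameter=pname,
            base_value=base_value,
            perturbed_values=[float(v) for v in values],
            interval=(float(interval[0]), float(interval[1])),
            rel_changes=rel_changes,
            directions=directions,
            qualitative_change=qual,
        ))
    return SensitivityReport(
        entries=entries, baseline_summaries=base_sum, threshold=threshold
    )


def radial_binning(field_values: np.ndarray, grid: RadialGrid,
                   bin_width: float = 0.15) -> pd.DataFrame:
    """Area-weighted mean of a spatial field over fixed-width radial bins.

    Mirrors the binning used for immunohistochemistry counts (pieces of
    roughly 0.15 cm along the radius).  Cells are assigned to bins by
    their center radius; the final bin absorbs any remainder up to
    ``r_max``.  Returns a frame with bin edges and the per-bin mean.
    """
    if bin_width <= 0:
        raise ValueError("radial_binning: bin_width must be positive")
    field_values = np.asarray(field_values, dtype=float)
    n_bins = int(np.ceil(grid.r_max / bin_width - 1e-12))
    starts = np.arange(n_bins) * bin_width
    ends = np.minimum(starts + bin_width, grid.r_max)
    idx = np.minimum(
        (grid.centers / bin_width).astype(int), n_bins - 1
    )
    area_sum = np.bincount(idx, weights=grid.cell_areas, minlength=n_bins)
    weighted = np.bincount(
        idx, weights=grid.cell_areas * field_values, minlength=n_bins
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(area_sum > 0, weighted / area_sum, np.nan)
    return pd.DataFrame({
        "bin_start_cm": starts,
        "bin_end_cm": ends,
        "mean": means,
    })


def load_binned_counts(path) -> pd.DataFrame:
    """Read experimentally binned positive-cell counts.

    Expected columns: ``bin_start_cm``, ``bin_end_cm``, ``day``,
    ``count`` — one row per radial interval and observation day, the
    format produced by immunohistochemistry image analysis.
    """
    df = pd.read_csv(path)
    required = {"bin_start_cm", "bin_end_cm", "day", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"binned-counts file is missing columns: {sorted(missing)}"
        )
    return df


def overlay_with_simulation(counts: pd.DataFrame, traj: Trajectory,
                            grids, field: str = "F") -> pd.DataFrame:
    """Attach the simulated counterpart to experimentally binned counts.

    For every row, the snapshot closest to ``day`` is binned (area-
    weighted mean of the chosen tracked output over the row's radial
    interval) into a new ``model_mean`` column, for side-by-side
    comparison of radial profiles.  Concentrations and positive-cell
    counts are on different scales, so the comparison is of shape, not
    magnitude.
    """
    out = counts.copy()
    snap_times = np.array([s.t for s in traj.snapshots])
    profiles: dict[int, np.ndarray] = {}

    def profile_at(day: float) -> np.ndarray:
        i = int(np.argmin(np.abs(snap_times - day)))
        if i not in profiles:
            profiles[i] = tracked_outputs(traj.snapshots[i], grids)[field]
        return profiles[i]

    radial = grids.radial
    means = []
    for row in out.itertuples(index=False):
        values = profile_at(row.day)
        mask = (radial.centers >= row.bin_start_cm) & (
            radial.centers < row.bin_end_cm
        )
        if not mask.any():
            means.append(np.nan)
            continue
        areas = radial.cell_areas[mask]
        means.append(float(areas @ values[mask] / areas.sum()))
    out["model_mean"] = means
    return out


def convergence_to_frame(report: ConvergenceReport) -> pd.DataFrame:
    rows = []
    for name, errs in report.errors.items():
        for count, err in zip(report.interval_counts, errs):
            rows.append({"variable": name, "n_r": count,
                         "relative_error": err})
    return pd.DataFrame(rows)


def sensitivity_to_frame(report: SensitivityReport) -> pd.DataFrame:
    rows = []
    for e in report.entries:
        for value, changes in e.rel_changes.items():
            for name, change in changes.items():
                rows.append({
                    "parameter": e.parameter,
                    "base_value": e.base_value,
                    "perturbed_value": value,
                    "output": name,
                    "relative_change": change,
                    "direction_in_interval": e.directions[name],
                    "qualitative_change": e.qualitative_change[value],
                })
    return pd.DataFrame(rows)
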