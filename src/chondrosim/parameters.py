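"""Parameter sets, domain constants, and numerics configuration.

The model describes chondrocyte state transitions and cytokine dynamics in
the superficial zone of articular cartilage after a single blunt impact.
Chemical species are reactive oxygen species (ROS, ``R``), alarmins/DAMPs
(``M``), a representative pro-inflammatory cytokine (IL-6, ``F``) and the
anti-inflammatory cytokine erythropoietin (EPO, ``P``); ``U`` is the
extracellular-matrix (ECM) density.  Cell compartments are healthy
unsignaled (``C_U``), healthy signaled / pre-catabolic (``C_T``, structured
by time-since-signaling), EPO-producing healthy (``C_E``), catabolic sick
(``S_T``, age-structured), EPOR-active sick (``S_A``) and necrotic
(``D_N``) chondrocytes.

All rate constants carry units of 1/day, diffusivities cm^2/day,
concentrations nanomolar, and cell densities cells/cm^2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ModelParams",
    "DomainConfig",
    "NumericsConfig",
    "default_params",
    "validate",
    "load_config",
    "save_config",
    "config_to_dict",
    "config_from_dict",
]


@dataclass
class ModelParams:
    """Rate, saturation and threshold constants of the lesion model.

    Defaults reproduce the published baseline parameterisation of the
    single-impact model.  ``kappa_1`` doubles as the rate scale of the
    delayed catabolic-to-EPOR-active transition (the same role ``kappa_2``
    plays for the pre-catabolic-to-EPO-producing transition).
    """

    # Diffusion coefficients, cm^2/day
    D_R: float = 0.1
    D_M: float = 0.05
    D_F: float = 0.05
    D_P: float = 0.005
    # Natural decay rates, 1/day
    delta_R: float = 60.0
    delta_M: float = 0.5545
    delta_F: float = 0.5545
    delta_P: float = 3.326
    # ECM degradation rate, 1/day
    delta_U: float = 0.0193
    # Per-cell chemical production rates, nanomolar cm^2 / (day cells)
    sigma_R: float = 0.0024
    sigma_M: float = 5.17e-7
    sigma_F: float = 2.35e-7
    sigma_P: float = 4.2e-5
    # Listed with the production rates; not referenced by the dynamics but
    # kept loadable so configuration files round-trip faithfully.
    sigma_U: float = 0.0154
    # IL-6 suppression saturation for EPO production, nanomolar
    Lambda: float = 0.5
    # Half-saturation constants, nanomolar
    lambda_R: float = 5.0
    lambda_M: float = 0.5
    lambda_F: float = 0.5
    lambda_P: float = 0.5
    # Recovery rates, 1/day
    alpha_1: float = 1.0
    alpha_2: float = 1.0
    # Signaling transition rates, 1/day
    beta_11: float = 100.0
    beta_12: float = 50.0
    beta_13: float = 10.0
    # Delayed-transition rate scales, 1/day
    kappa_1: float = 10.0
    kappa_2: float = 10.0
    # EPO threshold gating the anti-inflammatory switch, nanomolar
    P_c: float = 1.0
    # Apoptosis rates, 1/day
    mu_ST: float = 0.5
    mu_SA: float = 0.1
    # Necrotic clearance rate, 1/day
    mu_DN: float = 0.05
    # Transition ages (time since signaling at which the delayed transition
    # concentrates), days: tau_1 for S_T -> S_A, tau_2 for C_T -> C_E.
    tau_1: float = 0.5
    tau_2: float = 1.0
    # Transition-kernel shape: height gamma_0 (dimensionless) and spread
    # sigma_spread (days).  As sigma_spread -> 0 all cells switch exactly at
    # the transition age.
    gamma_0: float = 1.0
    sigma_spread: float = 0.05


@dataclass
class DomainConfig:
    """Geometry, initial-condition constants and output times."""

    r_max: float = 2.5  # explant radius, cm
    r_impact: float = 0.25  # radius of the impacted region, cm
    cell_density_0: float = 100_000.0  # initial healthy density, cells/cm^2
    U_0: float = 30.0  # initial ECM density, model units
    t_end: float = 14.0  # simulation horizon, days
    snapshot_times: tuple[float, ...] = (0.0, 1.0, 5.0, 7.0, 10.0, 14.0)

    def __post_init__(self) -> None:
        self.snapshot_times = tuple(float(t) for t in self.snapshot_times)


@dataclass
class NumericsConfig:
    """Discretization and adaptive time-stepping settings.

    The age grid truncates the time-since-signaling axis at ``a_cap``; the
    transition kernels drain the age-structured compartments shortly after
    their transition ages, so the mass reaching ``a_cap`` is negligible (it
    is tracked as a diagnostic).  ``tol`` controls the step-doubling local
    error estimate in a per-field relative max-norm.
    """

    n_r: int = 200  # radial intervals
    n_a: int = 129  # age intervals
    a_cap: float = 3.0  # maximum resolved age, days
    dt_init: float = 1e-4  # days
    dt_min: float = 1e-9  # days
    dt_max: float = 0.02  # days; additionally capped at the age spacing
    tol: float = 1e-5  # relative local-error tolerance
    seed: int = 0  # reserved; the model is deterministic


def default_params() -> ModelParams:
    """Return the baseline parameter set."""
    return ModelParams()


def validate(
    params: ModelParams, dom: DomainConfig, num: NumericsConfig
) -> list[str]:
    """Check all configuration invariants.

    Returns a list of human-readable diagnostics, one per violated
    invariant; an empty list means the configuration is consistent.
    """
    diags: list[str] = []

    positive_fields = [
        f.name
        for f in dataclasses.fields(ModelParams)
    ]
    for name in positive_fields:
        value = getattr(params, name)
        if not value > 0:
            diags.append(f"{name}: must be strictly positive, got {value!r}")

    if not 0 < dom.r_impact < dom.r_max:
        diags.append(
            f"r_impact: must satisfy 0 < r_impact < r_max, got "
            f"r_impact={dom.r_impact!r}, r_max={dom.r_max!r}"
        )
    if not dom.r_max > 0:
        diags.append(f"r_max: must be positive, got {dom.r_max!r}")
    if not dom.cell_density_0 > 0:
        diags.append(
            f"cell_density_0: must be positive, got {dom.cell_density_0!r}"
        )
    if not dom.U_0 > 0:
        diags.append(f"U_0: must be positive, got {dom.U_0!r}")
    if not dom.t_end > 0:
        diags.append(f"t_end: must be positive, got {dom.t_end!r}")
    snaps = list(dom.snapshot_times)
    if snaps != sorted(snaps):
        diags.append(f"snapshot_times: must be sorted, got {snaps!r}")
    if snaps and (snaps[0] < 0 or snaps[-1] > dom.t_end):
        diags.append(
            f"snapshot_times: must lie within [0, t_end], got {snaps!r} "
            f"with t_end={dom.t_end!r}"
        )

    if num.n_r < 4:
        diags.append(f"n_r: need at least 4 radial intervals, got {num.n_r!r}")
    if num.n_a < 4:
        diags.append(f"n_a: need at least 4 age intervals, got {num.n_a!r}")
    if not num.a_cap > max(params.tau_1, params.tau_2):
        diags.append(
            f"a_cap: must exceed the largest transition age "
            f"max(tau_1, tau_2)={max(params.tau_1, params.tau_2)!r}, "
            f"got {num.a_cap!r}"
        )
    if not num.dt_min <= num.dt_init <= num.dt_max:
        diags.append(
            f"dt_init: need dt_min <= dt_init <= dt_max, got "
            f"dt_min={num.dt_min!r}, dt_init={num.dt_init!r}, "
            f"dt_max={num.dt_max!r}"
        )
    if not num.tol > 0:
        diags.append(f"tol: must be positive, got {num.tol!r}")

    return diags


# --- configuration files -------------------------------------------------
#
# Format: a YAML mapping with three sections, `model`, `domain` and
# `numerics`, whose keys are exactly the dataclass field names above.
# Unknown sections or keys are an error (they usually indicate a typo).

_SECTIONS: dict[str, type] = {
    "model": ModelParams,
    "domain": DomainConfig,
    "numerics": NumericsConfig,
}


def config_to_dict(
    params: ModelParams, dom: DomainConfig, num: NumericsConfig
) -> dict[str, dict[str, Any]]:
    out: dict[str, dict[str, Any]] = {}
    for section, obj in (("model", params), ("domain", dom), ("numerics", num)):
        d = dataclasses.asdict(obj)
        if "snapshot_times" in d:
            d["snapshot_times"] = list(d["snapshot_times"])
        out[section] = d
    return out


def config_from_dict(
    data: dict[str, Any]
) -> tuple[ModelParams, DomainConfig, NumericsConfig]:
    if not isinstance(data, dict):
        raise ValueError("configuration root must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown configuration sections: {sorted(unknown)}")
    built = {}
    for section, cls in _SECTIONS.items():
        payload = data.get(section, {}) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        bad = set(payload) - names
        if bad:
            raise ValueError(
                f"unknown keys in section '{section}': {sorted(bad)}"
            )
        built[section] = cls(**payload)
    return built["model"], built["domain"], built["numerics"]


def load_config(
    path: str | Path,
) -> tuple[ModelParams, DomainConfig, NumericsConfig]:
    """Read a three-section YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def save_config(
    path: str | Path,
    params: ModelParams,
    dom: DomainConfig,
    num: NumericsConfig,
) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            config_to_dict(params, dom, num), fh, sort_keys=False
        )
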