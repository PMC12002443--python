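"""Model registry: every toxicokinetic model in the suite is declared by a
ModelInfo entry describing its state variables, parameters, derivative
outputs with units and state of matter, dosing routes, data requirements,
and steady-state / Monte Carlo capabilities.  Core functions look models up
here and never hard-code model specifics.

The ordering contract between ``derivative_output_names`` and what the
derivative routine actually returns is load-bearing: a permuted declaration
silently relabels outputs (e.g. reporting a ppmv column as µM), which is
why :func:`validate_model` probes the derivative with sentinel states and
checks the ordering explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ..chem import DataRequirements
from ..partition import LumpingScheme

__all__ = [
    "ModelInfo",
    "SteadyStateInfo",
    "MonteCarloInfo",
    "register_model",
    "get_model",
    "list_models",
    "validate_model",
    "evaluate_derivative",
    "RegistryError",
]


class RegistryError(KeyError):
    pass


@dataclass(frozen=True)
class SteadyStateInfo:
    analytic_css_func: Callable | str
    steady_state_compartment: str = "plasma"
    steady_state_units: str = "uM"
    css_dosing_param: str = "daily_dose"


@dataclass(frozen=True)
class MonteCarloInfo:
    calcpc: bool = True
    firstpass: bool = True
    httkpop_params: tuple[str, ...] = ()
    invitro_params: tuple[str, ...] = ("Clint", "fup")
    propagateuv_func: Callable | None = None


@dataclass(frozen=True)
class ModelInfo:
    name: str
    state_vars: tuple[str, ...]  # amounts, µmol unless declared otherwise
    param_names: tuple[str, ...]
    required_params: tuple[str, ...]  # chemical data fields needed
    derivative_output_names: tuple[str, ...]
    compartment_units: dict
    compartment_state: dict  # output -> "gas" | "liquid"
    routes: frozenset
    data_requirements: DataRequirements
    derivative: Callable | None = None  # (t, y, params, forcings) -> (dydt, aux)
    solver_param_order: tuple[str, ...] = ()
    input_var_names: tuple[str, ...] = ()
    default_monitor_vars: tuple[str, ...] = ("Cplasma",)
    accumulators: tuple[str, ...] = ()  # states excluded from the SS solve
    dose_targets: dict = field(default_factory=dict)  # route -> state var
    lumping_scheme: LumpingScheme = field(
        default_factory=lambda: LumpingScheme(lumps={})
    )
    steady_state: SteadyStateInfo | None = None
    mc: MonteCarloInfo | None = None
    solve_capable: bool = True

    def __post_init__(self) -> None:
        if self.derivative is not None:
            missing = set(self.state_vars) - set(self.derivative_output_names)
            if missing:
                raise ValueError(
                    f"{self.name}: derivative_output_names must include every "
                    f"state variable; missing {sorted(missing)}"
                )


_REGISTRY: dict[str, ModelInfo] = {}


def register_model(info: ModelInfo) -> ModelInfo:
    """Add a model to the registry; duplicate names are an error."""
    if info.name in _REGISTRY:
        raise RegistryError(f"model {info.name!r} already registered")
    _REGISTRY[info.name] = info
    return info


def get_model(name: str) -> ModelInfo:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise RegistryError(
            f"unknown model {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def list_models() -> list[str]:
    return sorted(_REGISTRY)


def _clear_registry_for_tests() -> dict[str, ModelInfo]:
    """Swap out the registry (tests only); returns the old one."""
    global _REGISTRY
    old, _REGISTRY = _REGISTRY, {}
    return old


def _restore_registry_for_tests(old: dict) -> None:
    global _REGISTRY
    _REGISTRY = old


def evaluate_derivative(model: str, t: float, state, params, forcings_at_t=None):
    """Evaluate a model's derivative routine at one point.

    ``state`` is amounts (µmol) matching ``state_vars``; ``params`` is a
    solver-parameter dict (per-day rates).  Returns (dstate_dt, aux dict).
    """
    info = get_model(model)
    if info.derivative is None:
        raise RegistryError(f"model {model!r} has no derivative (steady-state only)")
    state = np.asarray(state, dtype=float)
    if state.shape != (len(info.state_vars),):
        raise ValueError(
            f"state length {state.shape} does not match state_vars "
            f"({len(info.state_vars)})"
        )
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state")
    forcings_at_t = forcings_at_t or {}
    dydt, aux = info.derivative(t, state, params, forcings_at_t)
    return np.asarray(dydt, dtype=float), aux


def validate_model(info: ModelInfo, probe_params: dict | None = None) -> list[str]:
    """Validation report for a registry entry; empty list = valid.

    Checks (a) ordering agreement between the declared derivative outputs
    and the routine's actual outputs on a sentinel-state probe evaluation,
    (b) every output has a unit and a state of matter, (c) every route has
    a dosing target, (d) required_params ⊆ param_names.
    """
    failures: list[str] = []
    for out in info.derivative_output_names:
        if out not in info.compartment_units:
            failures.append(f"output {out!r} missing from compartment_units")
        if out not in info.compartment_state:
            failures.append(f"output {out!r} missing from compartment_state")
    for route in info.routes:
        if route == "inhalation":
            if not info.input_var_names:
                failures.append("inhalation route declared but no input/forcing variable")
        elif route not in info.dose_targets:
            failures.append(f"route {route!r} has no dosing target state")
    for rp in info.dose_targets.values():
        if rp not in info.state_vars:
            failures.append(f"dose target {rp!r} is not a state variable")

    if info.derivative is not None and probe_params is not None:
        # Probe with distinct sentinel amounts per state: the aux outputs
        # the routine returns must appear under the declared names, in the
        # declared order.
        sentinel = np.linspace(1.0, 2.0, len(info.state_vars))
        forc = {name: 0.0 for name in info.input_var_names}
        try:
            _, aux = info.derivative(0.0, sentinel, probe_params, forc)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(f"derivative probe raised: {exc!r}")
            return failures
        actual = list(aux)
        declared = list(info.derivative_output_names)
        if actual != declared:
            failures.append(
                "derivative output ordering mismatch: declared "
                f"{declared} but routine produced {actual}"
            )
        # state outputs must echo the probe amounts exactly
        for i, sv in enumerate(info.state_vars):
            if sv in aux and not np.isclose(aux[sv], sentinel[i]):
                failures.append(
                    f"state output {sv!r} does not track its state amount "
                    f"(sentinel {sentinel[i]} -> {aux[sv]})"
                )
    return failures
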