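"""Analytic and numerical quasi-steady-state plasma concentration.

Under repeated discrete dosing a linear toxicokinetic model settles into a
periodic orbit whose day-average equals the steady state of the same model
under an equivalent continuous infusion.  ``calc_analytic_css`` exploits
this: for ODE models the (linear) right-hand side is probed column by
column to build the system matrix A, and A x = -b is solved for the
infusion input b — no hand-derived per-model formula to transcribe wrongly.
``calc_css`` instead simulates repeated dosing (default three doses per
day) until the day-averaged concentration stops changing, and reports the
days needed to get there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models.dosing import DoseRegimen
from .models.registry import get_model
from .models.solve import solve_model, solver_params
from .parameterize import ParameterSet, parameterize_model
from .units import Quantity, UnitContext, convert_units, scale_dosing

__all__ = [
    "SteadyStateResult",
    "calc_analytic_css",
    "calc_css",
    "CapabilityError",
]


class CapabilityError(ValueError):
    """The model does not declare the requested steady-state capability."""


@dataclass
class SteadyStateResult:
    css: float  # steady-state concentration in `units`
    units: str
    compartment: str
    days_to_steady: float
    avg_conc: float  # µM day-average at steady state
    ratio_avg_to_analytic: float | None
    converged: bool
    dose_events_per_day: float = float("nan")


def _resolve_params(model, chem, species, params, options, lib):
    if params is None:
        if chem is None:
            raise ValueError("provide a chemical or a ParameterSet")
        params = parameterize_model(model, chem, species, options, lib=lib)
    return params


def _dose_rate_umol_per_day(dose_rate: float, units: str, BW: float, MW: float) -> float:
    q = Quantity(dose_rate, units)
    if "/kg" in units:
        q = scale_dosing(q, BW)
    if not q.unit.endswith("/day"):
        raise ValueError(f"dose rate unit {units!r} must be a per-day rate")
    amount_unit = q.unit[: -len("/day")]
    umol = convert_units(Quantity(q.value, amount_unit), "umol", UnitContext(MW=MW)).value
    return umol


def linear_system_css(model: str, params: ParameterSet, dose_rate_umol_per_day: float) -> float:
    """Steady state of a linear ODE model under continuous oral infusion (µM).

    Accumulator states (cleared/exhaled/AUC) are excluded; the remaining
    linear system A x = -b is solved exactly.  Raises if the system is
    singular (non-clearing chemical: no finite steady state).
    """
    info = get_model(model)
    if info.derivative is None:
        raise CapabilityError(f"model {model!r} has no ODE; use its closed form")
    p = solver_params(params)
    keep = [i for i, sv in enumerate(info.state_vars) if sv not in info.accumulators]
    n_all = len(info.state_vars)
    n = len(keep)
    zero = np.zeros(n_all)
    forc = {name: 0.0 for name in info.input_var_names}
    f0, _ = info.derivative(0.0, zero, p, forc)
    A = np.empty((n, n))
    for j_red, j in enumerate(keep):
        e = zero.copy()
        e[j] = 1.0
        fj, _ = info.derivative(0.0, e, p, forc)
        A[:, j_red] = (np.asarray(fj) - np.asarray(f0))[keep]
    b = np.asarray(f0)[keep].copy()
    target = info.dose_targets["oral"]
    b[keep.index(info.state_vars.index(target))] += dose_rate_umol_per_day
    try:
        x_red = np.linalg.solve(A, -b)
    except np.linalg.LinAlgError:
        raise ZeroDivisionError(
            f"{model}: steady-state system singular (non-clearing chemical)"
        ) from None
    if np.any(x_red < -1e-6 * max(1.0, np.abs(x_red).max())):
        raise ZeroDivisionError(
            f"{model}: steady state not attainable (negative amounts); "
            "chemical does not clear"
        )
    x = np.zeros(n_all)
    x[keep] = x_red
    _, aux = info.derivative(0.0, x, p, forc)
    compartment = info.steady_state.steady_state_compartment if info.steady_state else "plasma"
    key = "Cplasma" if compartment == "plasma" else compartment
    return float(aux[key])


def calc_analytic_css(
    model: str,
    chem=None,
    species: str = "Human",
    dose_rate: float = 1.0,
    dose_units: str = "mg/kg/day",
    output_units: str = "uM",
    params: ParameterSet | None = None,
    options: dict | None = None,
    lib=None,
) -> float:
    """Quasi-steady-state plasma concentration for a constant oral dose rate."""
    info = get_model(model)
    if info.steady_state is None:
        raise CapabilityError(
            f"model {model!r} declares no analytic steady state"
        )
    params = _resolve_params(model, chem, species, params, options, lib)
    rate = _dose_rate_umol_per_day(dose_rate, dose_units, params["BW"], params["MW"])
    func = info.steady_state.analytic_css_func
    if func == "linear_system":
        css_uM = linear_system_css(model, params, rate)
    else:
        css_uM = func(params.values, rate)
    if output_units == "uM":
        return css_uM
    ctx = UnitContext(MW=params["MW"])
    return convert_units(Quantity(css_uM, "uM"), output_units, ctx).value


def calc_css(
    model: str,
    chem=None,
    species: str = "Human",
    daily_dose: float = 1.0,
    dose_units: str = "mg/kg/day",
    doses_per_day: int = 3,
    tolerance: float = 0.01,
    max_days: int = 180,
    params: ParameterSet | None = None,
    options: dict | None = None,
    lib=None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> SteadyStateResult:
    """Numerical quasi-steady state under repeated dosing (default 3×/day).

    Simulates day by day; steady state is declared on the first day whose
    day-averaged plasma concentration changes by less than ``tolerance``
    (relative) from the previous day.  If the horizon is exceeded the
    partial result is returned flagged non-converged.
    """
    info = get_model(model)
    if not info.solve_capable:
        raise CapabilityError(f"model {model!r} is not solve-capable")
    params = _resolve_params(model, chem, species, params, options, lib)

    regimen = DoseRegimen(
        route="oral",
        daily_dose=daily_dose,
        doses_per_day=doses_per_day,
        input_units=dose_units,
    )
    # Day-averaged concentration from the model's own AUC accumulator
    # (exact integral to solver tolerance — no quadrature bias from the
    # sharp absorption peaks): avg over day n = AUC(n+1) - AUC(n).
    days_to_steady = None
    day_avgs: list[float] = []
    events_per_day = 0
    window = 10
    t_done = 0
    state = None
    while t_done < max_days and days_to_steady is None:
        t_hi = min(t_done + window, max_days)
        times = np.arange(float(t_done), float(t_hi) + 0.5)
        res = solve_model(
            model,
            params=params,
            times=times,
            regimen=regimen,
            monitor_vars=("Cplasma", "AUC"),
            rtol=rtol,
            atol=atol,
            initial_state=state,
            exclude_events_at_start=t_done > 0,
        )
        state = res.metadata["state_records"][-1]
        auc = res.column("AUC")
        if t_done == 0:
            events_per_day = sum(1 for t, _v, _a in res.dose_log if 0.0 <= t < 1.0)
        for k in range(len(auc) - 1):
            day_avgs.append(float(auc[k + 1] - auc[k]))
            if len(day_avgs) >= 2 and day_avgs[-2] > 0:
                rel = abs(day_avgs[-1] - day_avgs[-2]) / day_avgs[-2]
                if rel < tolerance:
                    days_to_steady = float(t_done + k + 1)
                    break
        t_done = t_hi

    converged = days_to_steady is not None
    if not converged:
        days_to_steady = float(max_days)
    avg = day_avgs[-1] if day_avgs else 0.0

    analytic = None
    try:
        analytic = calc_analytic_css(
            model, params=params, dose_rate=daily_dose, dose_units=dose_units
        )
    except (CapabilityError, ZeroDivisionError):
        analytic = None
    ss = info.steady_state
    return SteadyStateResult(
        css=avg,
        units="uM",
        compartment=(ss.steady_state_compartment if ss else "plasma"),
        days_to_steady=days_to_steady,
        avg_conc=avg,
        ratio_avg_to_analytic=(avg / analytic if analytic else None),
        converged=converged,
        dose_events_per_day=float(events_per_day),
    )
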