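"""Three-compartment steady-state model.

A steady-state-only IVIVE model (no ODE): the quasi-steady-state plasma
concentration under a constant oral dose rate is

    Css = dose_rate_molar / (fup * GFR + CLh)

with renal filtration of the unbound fraction and well-stirred hepatic
clearance as the only elimination pathways.  The registry marks it
solve-incapable and steady-state-capable; it is the default model for
chemical eligibility queries.
"""

from __future__ import annotations

from ..chem import DataRequirements
from ..partition import LumpingScheme
from .registry import ModelInfo, MonteCarloInfo, SteadyStateInfo, register_model

PARAM_NAMES = ("BW", "MW", "fup", "Clint", "Clint_w", "CLh", "GFR", "Rblood2plasma")


def analytic_css(params: dict, dose_rate_umol_per_day: float) -> float:
    """Css (µM) for a constant molar oral dose rate (µmol/day)."""
    cl_total_L_per_day = 24.0 * (params["fup"] * params["GFR"] + params["CLh"])
    if cl_total_L_per_day <= 0:
        raise ZeroDivisionError(
            "non-clearing chemical: fup*GFR + CLh = 0, steady state unbounded"
        )
    return dose_rate_umol_per_day / cl_total_L_per_day


INFO = register_model(
    ModelInfo(
        name="3compartmentss",
        state_vars=(),
        param_names=PARAM_NAMES,
        required_params=("MW", "fup", "Clint"),
        derivative_output_names=(),
        compartment_units={"Cplasma": "uM"},
        compartment_state={"Cplasma": "liquid"},
        routes=frozenset({"oral"}),
        data_requirements=DataRequirements(
            required_params=("MW", "fup", "Clint"),
            exclude_fup_zero=False,
            log_henry_threshold=-4.5,
        ),
        derivative=None,
        default_monitor_vars=("Cplasma",),
        dose_targets={},
        lumping_scheme=LumpingScheme(
            lumps={"gut": ("gut",), "liver": ("liver",), "kidney": ("kidney",), "lung": ("lung",)}
        ),
        steady_state=SteadyStateInfo(analytic_css_func=analytic_css),
        mc=MonteCarloInfo(calcpc=False, firstpass=False),
        solve_capable=False,
    )
)
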