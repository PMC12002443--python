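"""Empirical one-compartment model.

A single well-mixed distribution volume (plasma-referenced Vdist derived
from the tissue partition coefficients) with first-order elimination
``kelim = (CLh + fup*GFR) / Vdist`` and first-order oral absorption from
the gut lumen.  The closed form for an iv bolus,
``C(t) = dose/Vdist * exp(-kelim t)``, is the standard oracle for the
solver machinery.
"""

from __future__ import annotations

import numpy as np

from ..chem import DataRequirements
from ..partition import LumpingScheme
from .registry import ModelInfo, MonteCarloInfo, SteadyStateInfo, register_model

STATE_VARS = ("Agutlumen", "Acompartment", "Ametabolized", "Aunabsorbed", "AUC")

PARAM_NAMES = (
    "BW", "MW", "fup", "Rblood2plasma", "Vdist", "kelim", "ka",
    "Fabs", "Fgut", "Fhep", "CLh", "GFR",
)

AUX_OUTPUTS = ("Ccompartment", "Cplasma")


def derivative(t, y, p, forcings):
    agl, acomp, amet, aunab, auc = y
    absorbed_frac = p["Fabs"] * p["Fgut"]
    d_agl = -p["ka"] * agl
    eliminated = p["kelim"] * acomp
    d_acomp = p["ka"] * absorbed_frac * agl - eliminated
    d_aunab = p["ka"] * (1.0 - absorbed_frac) * agl
    ccomp = acomp / p["Vdist"]
    dydt = np.array([d_agl, d_acomp, eliminated, d_aunab, ccomp])
    aux = {
        "Agutlumen": agl, "Acompartment": acomp, "Ametabolized": amet,
        "Aunabsorbed": aunab, "AUC": auc,
        "Ccompartment": ccomp, "Cplasma": ccomp,
    }
    return dydt, aux


INFO = register_model(
    ModelInfo(
        name="1compartment",
        state_vars=STATE_VARS,
        param_names=PARAM_NAMES,
        required_params=("MW", "logP", "fup", "Clint"),
        derivative_output_names=(*STATE_VARS, *AUX_OUTPUTS),
        compartment_units={
            **{sv: "umol" for sv in STATE_VARS},
            "AUC": "uM*day",
            "Ccompartment": "uM",
            "Cplasma": "uM",
        },
        compartment_state={name: "liquid" for name in (*STATE_VARS, *AUX_OUTPUTS)},
        routes=frozenset({"oral", "iv"}),
        data_requirements=DataRequirements(
            required_params=("MW", "logP", "fup", "Clint"),
            exclude_fup_zero=False,
            log_henry_threshold=-4.5,
        ),
        derivative=derivative,
        solver_param_order=PARAM_NAMES,
        default_monitor_vars=("Cplasma", "AUC"),
        accumulators=("Ametabolized", "Aunabsorbed", "AUC"),
        dose_targets={"oral": "Agutlumen", "iv": "Acompartment"},
        lumping_scheme=LumpingScheme(
            lumps={"gut": ("gut",), "liver": ("liver",), "kidney": ("kidney",), "lung": ("lung",)}
        ),
        steady_state=SteadyStateInfo(analytic_css_func="linear_system"),
        mc=MonteCarloInfo(calcpc=True, firstpass=True),
    )
)
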