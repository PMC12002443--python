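"""Perfusion-limited whole-body PBTK model.

Compartments (state amounts, µmol): gut lumen, gut, liver, kidney, lung,
rest-of-body, arterial and venous blood, plus cumulative accumulators for
renal filtrate (urine), hepatic metabolism, unabsorbed oral dose, and the
plasma-concentration AUC.  Blood flows connect arterial blood to each
perfused tissue and back through venous blood; venous blood passes through
the lung tissue before becoming arterial.  Tissues are perfusion-limited:
blood leaves each tissue in equilibrium with it, at concentration
``C_tissue * Rb2p / (Kp * fup)`` (Kp is tissue:unbound-plasma).

Liver receives the hepatic artery plus the gut outflow (portal vein);
metabolism clears the unbound liver concentration at the scaled intrinsic
clearance, which reproduces well-stirred hepatic extraction at steady
state.  Kidney filters the unbound kidney concentration at GFR.  Oral
absorption drains the gut lumen first-order; the fraction Fabs*Fgut enters
gut tissue and the rest accumulates as unabsorbed, so mass balance is
exact by construction.
"""

from __future__ import annotations

import numpy as np

from ..chem import DataRequirements
from ..partition import LumpingScheme
from .registry import ModelInfo, MonteCarloInfo, SteadyStateInfo, register_model

STATE_VARS = (
    "Agutlumen",
    "Agut",
    "Aliver",
    "Akidney",
    "Alung",
    "Arest",
    "Aart",
    "Aven",
    "Atubules",
    "Ametabolized",
    "Aunabsorbed",
    "AUC",
)

PARAM_NAMES = (
    "BW", "MW", "fup", "Clint", "Clint_w", "CLh", "Rblood2plasma", "hematocrit",
    "Fabs", "Fgut", "Fhep", "ka", "Qcardiac", "GFR",
    "Qgut", "Qliver", "Qkidney", "Qrest", "Qlung",
    "Vgut", "Vliver", "Vkidney", "Vlung", "Vrest", "Vart", "Vven",
    "Kgut2pu", "Kliver2pu", "Kkidney2pu", "Klung2pu", "Krest2pu", "Krbc2pu",
)

AUX_OUTPUTS = ("Cgut", "Cliver", "Ckidney", "Clung", "Crest", "Cart", "Cven", "Cplasma")


def derivative(t, y, p, forcings):
    """RHS; p carries per-day flows/rates.  Returns (dydt, ordered aux)."""
    (agl, agut, aliv, akid, alung, arest, aart, aven,
     atub, amet, aunab, auc) = y

    fup = p["fup"]
    rb2p = p["Rblood2plasma"]

    cgut = agut / p["Vgut"]
    cliv = aliv / p["Vliver"]
    ckid = akid / p["Vkidney"]
    clung = alung / p["Vlung"]
    crest = arest / p["Vrest"]
    cart = aart / p["Vart"]
    cven = aven / p["Vven"]

    def blood_out(c_tissue, kp):
        return c_tissue * rb2p / (kp * fup)

    cgut_out = blood_out(cgut, p["Kgut2pu"])
    cliv_out = blood_out(cliv, p["Kliver2pu"])
    ckid_out = blood_out(ckid, p["Kkidney2pu"])
    clung_out = blood_out(clung, p["Klung2pu"])
    crest_out = blood_out(crest, p["Krest2pu"])

    absorbed_frac = p["Fabs"] * p["Fgut"]
    d_agl = -p["ka"] * agl
    d_agut = p["ka"] * absorbed_frac * agl + p["Qgut"] * (cart - cgut_out)
    d_aunab = p["ka"] * (1.0 - absorbed_frac) * agl

    q_liver_total = p["Qliver"] + p["Qgut"]
    metab = p["Clint_w"] * cliv / p["Kliver2pu"]  # clears unbound tissue conc
    d_aliv = p["Qliver"] * cart + p["Qgut"] * cgut_out - q_liver_total * cliv_out - metab

    filtration = p["GFR"] * ckid / p["Kkidney2pu"]
    d_akid = p["Qkidney"] * (cart - ckid_out) - filtration

    d_alung = p["Qcardiac"] * (cven - clung_out)
    d_aart = p["Qcardiac"] * clung_out - p["Qcardiac"] * cart
    d_arest = p["Qrest"] * (cart - crest_out)
    d_aven = (
        q_liver_total * cliv_out
        + p["Qkidney"] * ckid_out
        + p["Qrest"] * crest_out
        - p["Qcardiac"] * cven
    )

    cplasma = cven / rb2p
    dydt = np.array([
        d_agl, d_agut, d_aliv, d_akid, d_alung, d_arest, d_aart, d_aven,
        filtration, metab, d_aunab, cplasma,
    ])
    aux = {
        "Agutlumen": agl, "Agut": agut, "Aliver": aliv, "Akidney": akid,
        "Alung": alung, "Arest": arest, "Aart": aart, "Aven": aven,
        "Atubules": atub, "Ametabolized": amet, "Aunabsorbed": aunab, "AUC": auc,
        "Cgut": cgut, "Cliver": cliv, "Ckidney": ckid, "Clung": clung,
        "Crest": crest, "Cart": cart, "Cven": cven, "Cplasma": cplasma,
    }
    return dydt, aux


COMPARTMENT_UNITS = {
    **{sv: "umol" for sv in STATE_VARS},
    "AUC": "uM*day",
    **{c: "uM" for c in AUX_OUTPUTS},
}
COMPARTMENT_STATE = {name: "liquid" for name in (*STATE_VARS, *AUX_OUTPUTS)}

INFO = register_model(
    ModelInfo(
        name="pbtk",
        state_vars=STATE_VARS,
        param_names=PARAM_NAMES,
        required_params=("MW", "logP", "fup", "Clint"),
        derivative_output_names=(*STATE_VARS, *AUX_OUTPUTS),
        compartment_units=COMPARTMENT_UNITS,
        compartment_state=COMPARTMENT_STATE,
        routes=frozenset({"oral", "iv"}),
        data_requirements=DataRequirements(
            required_params=("MW", "logP", "fup", "Clint"),
            exclude_fup_zero=False,
            log_henry_threshold=-4.5,
        ),
        derivative=derivative,
        solver_param_order=PARAM_NAMES,
        default_monitor_vars=("Cplasma", "AUC"),
        accumulators=("Atubules", "Ametabolized", "Aunabsorbed", "AUC"),
        dose_targets={"oral": "Agutlumen", "iv": "Aven"},
        lumping_scheme=LumpingScheme(
            lumps={"gut": ("gut",), "liver": ("liver",), "kidney": ("kidney",), "lung": ("lung",)}
        ),
        steady_state=SteadyStateInfo(analytic_css_func="linear_system"),
        mc=MonteCarloInfo(
            calcpc=True,
            firstpass=True,
            httkpop_params=(
                "BW", "Qcardiac", "GFR", "Qgut", "Qliver", "Qkidney", "Qrest", "Qlung",
                "Vgut", "Vliver", "Vkidney", "Vlung", "Vrest", "Vart", "Vven", "Clint_w",
            ),
        ),
    )
)
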