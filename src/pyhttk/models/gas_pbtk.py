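"""Gas-inhalation PBTK model.

Extends the perfusion-limited PBTK structure with alveolar gas exchange
and a mucus/upper-respiratory-tract compartment.  Venous blood returning
to the lung equilibrates with alveolar air assuming steady-state exchange:

    C_exch = (Qalv * C_inh_alv + QC * C_ven) / (QC + Qalv / Kblood2air)

where ``C_inh_alv`` is the inhaled air concentration after a fraction
``fdep`` deposits in the mucus lining, and Kblood2air is derived from the
Henry's law constant at body temperature.  End-exhaled air is in
equilibrium with post-exchange blood (C_exch / Kblood2air) and is reported
in both µM and ppmv.  Mucus-deposited chemical desorbs first-order into
the gut lumen (swallowed).  Cumulative inhaled and exhaled amounts are
tracked so the mass balance closes exactly.

With zero air exposure, no deposition, and a very large Kblood2air the
model collapses to the oral PBTK kinetics.
"""

from __future__ import annotations

import numpy as np

from ..chem import DataRequirements
from ..partition import LumpingScheme
from ..units import R_L_ATM
from .registry import ModelInfo, MonteCarloInfo, register_model

STATE_VARS = (
    "Agutlumen",
    "Agut",
    "Aliver",
    "Akidney",
    "Alung",
    "Arest",
    "Aart",
    "Aven",
    "Amucus",
    "Atubules",
    "Ametabolized",
    "Aunabsorbed",
    "Aexhaled",
    "Ainhaled",
    "AUC",
)

PARAM_NAMES = (
    "BW", "MW", "fup", "Clint", "Clint_w", "CLh", "Rblood2plasma", "hematocrit",
    "Fabs", "Fgut", "Fhep", "ka", "Qcardiac", "Qalv", "GFR",
    "Qgut", "Qliver", "Qkidney", "Qrest", "Qlung",
    "Vgut", "Vliver", "Vkidney", "Vlung", "Vrest", "Vart", "Vven",
    "Kgut2pu", "Kliver2pu", "Kkidney2pu", "Klung2pu", "Krest2pu", "Krbc2pu",
    "Kblood2air", "Kwater2air", "kdes", "fdep",
)

AUX_OUTPUTS = (
    "Cgut", "Cliver", "Ckidney", "Clung", "Crest", "Cart", "Cven", "Cplasma",
    "Cendexh", "Cendexhppmv",
)

#: ambient temperature used for the ppmv report of exhaled breath
AMBIENT_K = 298.15


def derivative(t, y, p, forcings):
    (agl, agut, aliv, akid, alung, arest, aart, aven, amuc,
     atub, amet, aunab, aexh, ainh, auc) = y

    fup = p["fup"]
    rb2p = p["Rblood2plasma"]
    cinh = forcings.get("Cinh", 0.0)  # µM in inhaled air

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

    # upper respiratory tract: deposition into mucus, desorption to gut lumen
    cinh_alv = (1.0 - p["fdep"]) * cinh
    deposit = p["Qalv"] * p["fdep"] * cinh
    desorb = p["kdes"] * amuc

    qc, qalv, kb2a = p["Qcardiac"], p["Qalv"], p["Kblood2air"]
    c_exch = (qalv * cinh_alv + qc * cven) / (qc + qalv / kb2a)
    c_exhaled = c_exch / kb2a
    exhale = qalv * c_exhaled
    inhale_gross = qalv * cinh

    absorbed_frac = p["Fabs"] * p["Fgut"]
    d_agl = -p["ka"] * agl + desorb
    d_agut = p["ka"] * absorbed_frac * agl + p["Qgut"] * (cart - cgut_out)
    d_aunab = p["ka"] * (1.0 - absorbed_frac) * agl

    q_liver_total = p["Qliver"] + p["Qgut"]
    metab = p["Clint_w"] * cliv / p["Kliver2pu"]
    d_aliv = p["Qliver"] * cart + p["Qgut"] * cgut_out - q_liver_total * cliv_out - metab

    filtration = p["GFR"] * ckid / p["Kkidney2pu"]
    d_akid = p["Qkidney"] * (cart - ckid_out) - filtration

    # post-exchange blood perfuses lung tissue, then becomes arterial
    d_alung = qc * (c_exch - clung_out)
    d_aart = qc * clung_out - qc * cart
    d_arest = p["Qrest"] * (cart - crest_out)
    d_aven = (
        q_liver_total * cliv_out
        + p["Qkidney"] * ckid_out
        + p["Qrest"] * crest_out
        - qc * cven
    )
    d_amuc = deposit - desorb

    cplasma = cven / rb2p
    dydt = np.array([
        d_agl, d_agut, d_aliv, d_akid, d_alung, d_arest, d_aart, d_aven,
        d_amuc, filtration, metab, d_aunab, exhale, inhale_gross, cplasma,
    ])
    aux = {
        "Agutlumen": agl, "Agut": agut, "Aliver": aliv, "Akidney": akid,
        "Alung": alung, "Arest": arest, "Aart": aart, "Aven": aven,
        "Amucus": amuc, "Atubules": atub, "Ametabolized": amet,
        "Aunabsorbed": aunab, "Aexhaled": aexh, "Ainhaled": ainh, "AUC": auc,
        "Cgut": cgut, "Cliver": cliv, "Ckidney": ckid, "Clung": clung,
        "Crest": crest, "Cart": cart, "Cven": cven, "Cplasma": cplasma,
        "Cendexh": c_exhaled,
        "Cendexhppmv": c_exhaled * R_L_ATM * AMBIENT_K,
    }
    return dydt, aux


COMPARTMENT_UNITS = {
    **{sv: "umol" for sv in STATE_VARS},
    "AUC": "uM*day",
    **{c: "uM" for c in AUX_OUTPUTS},
    "Cendexhppmv": "ppmv",
}
COMPARTMENT_STATE = {
    **{name: "liquid" for name in (*STATE_VARS, *AUX_OUTPUTS)},
    "Cendexh": "gas",
    "Cendexhppmv": "gas",
    "Aexhaled": "gas",
    "Ainhaled": "gas",
}

INFO = register_model(
    ModelInfo(
        name="gas_pbtk",
        state_vars=STATE_VARS,
        param_names=PARAM_NAMES,
        required_params=("MW", "logP", "fup", "Clint", "logHenry"),
        derivative_output_names=(*STATE_VARS, *AUX_OUTPUTS),
        compartment_units=COMPARTMENT_UNITS,
        compartment_state=COMPARTMENT_STATE,
        routes=frozenset({"oral", "iv", "inhalation"}),
        data_requirements=DataRequirements(
            required_params=("MW", "logP", "fup", "Clint", "logHenry"),
            exclude_fup_zero=False,
            log_henry_threshold=None,  # applicable to volatiles by design
        ),
        derivative=derivative,
        solver_param_order=PARAM_NAMES,
        input_var_names=("Cinh",),
        default_monitor_vars=("Cplasma", "Cendexh", "Cendexhppmv", "AUC"),
        accumulators=(
            "Atubules", "Ametabolized", "Aunabsorbed", "Aexhaled", "Ainhaled", "AUC",
        ),
        dose_targets={"oral": "Agutlumen", "iv": "Aven"},
        lumping_scheme=LumpingScheme(
            lumps={"gut": ("gut",), "liver": ("liver",), "kidney": ("kidney",), "lung": ("lung",)}
        ),
        steady_state=None,  # no analytic steady state for the gas model
        mc=MonteCarloInfo(calcpc=True, firstpass=True),
    )
)
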