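"""Resolve a chemical + species physiology into a complete, unit-consistent
parameter set for each registered model.

The resolution chain: raw in vitro data (with the 0.5% default for failed
fup assays and the hepatocyte-assay binding correction for Clint) ->
tissue partitioning (component model + lumping scheme) -> blood:plasma
cascade -> hepatic clearance (well-stirred) -> oral bioavailability
(Caco-2 curve, 1% gut clearance rule, first-pass hepatic extraction) ->
allometrically scaled flows and volumes.  Parameterization is a pure,
deterministic function of (chemical, species, options, constants files).
"""

from __future__ import annotations

import importlib.resources as _res
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (
    DEFAULT_FUP,
    ChemicalLibrary,
    ChemicalRecord,
    MissingDataError,
    get_field,
)
from .partition import (
    calc_fup_correction,
    load_partition_config,
    load_tissue_table,
    lump_tissues,
    predict_partitioning_schmitt,
    resolve_rblood2plasma,
)
from .units import VOCABULARY, R_L_ATM

__all__ = [
    "PhysiologyTable",
    "ParameterSet",
    "load_physiology",
    "calc_hep_fu",
    "calc_hep_clearance",
    "calc_oral_bioavailability",
    "parameterize_model",
    "parameterize_gas_model",
    "ALLOMETRIC_EXPONENT",
]

#: 3/4-power allometric exponent for flows, ventilation and GFR.
ALLOMETRIC_EXPONENT = 0.75

#: Default first-order oral absorption rate (1/h).
DEFAULT_KA_PER_H = 2.18

# Caco-2 -> fraction absorbed: logistic in log10(Papp), configurable
CACO2_CURVE = {"midpoint_log10_papp": 0.0, "slope": 1.0}

# hepatocyte-assay binding: fu_hep = 1/(1 + scale*density*10^(slope*logP))
HEP_FU = {"scale_per_1e6_per_mL": 0.005, "logp_slope": 0.4}


@dataclass(frozen=True)
class PhysiologyTable:
    """Species physiology constants (per-kg or allometric coefficients)."""

    species: str
    BW: float  # kg
    QC: float  # L/h/kg^0.75 cardiac output coefficient
    Qalv: float  # L/h/kg^0.75 alveolar ventilation coefficient
    hct: float
    GFR: float  # L/h/kg^0.75
    liver_mass_frac: float  # g/kg BW
    hepatocellularity: float  # 1e6 cells / g liver
    body_temperature: float  # K
    Vart_frac: float  # L/kg
    Vven_frac: float  # L/kg

    def __post_init__(self) -> None:
        if not (0.0 < self.hct < 1.0):
            raise ValueError("hct must lie in (0, 1)")
        for name in ("BW", "QC", "Qalv", "GFR", "liver_mass_frac",
                     "hepatocellularity", "body_temperature", "Vart_frac", "Vven_frac"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def load_physiology(species: str = "Human", path=None) -> PhysiologyTable:
    if path is None:
        path = _res.files("pyhttk.data") / "physiology.csv"
    df = pd.read_csv(path)
    if species not in df.columns:
        raise KeyError(f"species {species!r} not in physiology table ({list(df.columns[2:-1])})")
    vals = dict(zip(df["parameter"], df[species].astype(float)))
    return PhysiologyTable(species=species, **vals)


@dataclass
class ParameterSet:
    """Fully resolved, unit-tagged model parameters."""

    model: str
    species: str
    values: dict[str, float] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def audit_units(self) -> list[str]:
        """Names whose declared unit is outside the controlled vocabulary."""
        bad = [k for k, u in self.units.items() if u not in VOCABULARY]
        bad += [k for k in self.values if k not in self.units]
        return bad

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            self.model, self.species, dict(self.values), dict(self.units), dict(self.provenance)
        )


def calc_hep_fu(chem: ChemicalRecord, assay_density: float = 1.0) -> float:
    """Fraction unbound in the hepatocyte clearance assay.

    Lipophilic chemicals associate with hepatocyte membranes/protein in
    the incubation, depressing the apparent intrinsic clearance.  Modeled
    as a logistic association increasing with logP and cell density
    (``assay_density`` in 1e6 cells/mL); hydrophilic limit -> 1.
    """
    logp = chem.logP if chem.logP is not None else 0.0
    assoc = HEP_FU["scale_per_1e6_per_mL"] * assay_density * 10.0 ** (HEP_FU["logp_slope"] * logp)
    return 1.0 / (1.0 + assoc)


def scale_clint_to_liver(clint: float, physiology: PhysiologyTable) -> float:
    """Scale assay Clint (uL/min/1e6 cells) to whole-liver L/h."""
    liver_g = physiology.liver_mass_frac * physiology.BW
    return clint * physiology.hepatocellularity * liver_g * 60.0 * 1e-6


def calc_hep_clearance(
    clint: float,
    fup: float,
    physiology: PhysiologyTable,
    model: str = "well-stirred",
    q_liver: float | None = None,
    fu_hep: float = 1.0,
) -> float:
    """Whole-liver hepatic clearance (L/h) from assay Clint.

    Clint is corrected for assay binding (/fu_hep), scaled to the whole
    liver, then the well-stirred model gives

        CLh = Q_liver * fup * Clint_w / (Q_liver + fup * Clint_w)

    which saturates at the liver blood flow.
    """
    if model != "well-stirred":
        raise ValueError(f"unknown hepatic scaling model {model!r}")
    if clint < 0:
        raise ValueError("Clint must be >= 0")
    clint_w = scale_clint_to_liver(clint / fu_hep, physiology)
    if q_liver is None:
        q_liver = total_liver_flow(physiology)
    num = q_liver * fup * clint_w
    return num / (q_liver + fup * clint_w) if num > 0 else 0.0


def total_liver_flow(physiology: PhysiologyTable, tissues=None) -> float:
    """Total liver blood flow (portal + hepatic artery), L/h."""
    tissues = tissues if tissues is not None else load_tissue_table()
    frac = sum(t.flow_frac_QC for t in tissues if t.tissue in ("gut", "liver"))
    return frac * physiology.QC * physiology.BW**ALLOMETRIC_EXPONENT


def caco2_to_fabs(papp: float, curve: dict | None = None) -> float:
    """Fraction absorbed from Caco-2 apparent permeability (1e-6 cm/s).

    Logistic in log10(Papp) with configurable midpoint and slope.
    """
    curve = curve or CACO2_CURVE
    x = np.log10(max(papp, 1e-12))
    return float(1.0 / (1.0 + 10.0 ** (-curve["slope"] * (x - curve["midpoint_log10_papp"]))))


def calc_oral_bioavailability(
    chem: ChemicalRecord,
    fup: float,
    clint_w: float,
    q_liver: float,
    rb2p: float,
    caco2_curve: dict | None = None,
) -> tuple[float, float, float, dict]:
    """(Fabs, Fgut, Fhep) for the oral route, with provenance.

    Fabs comes from the Caco-2 permeability curve when a measurement
    exists, else defaults to 1.  Fgut uses a gut intrinsic clearance equal
    to 1% of the scaled hepatic Clint competing with absorption into
    portal blood.  Fhep = Q_liver / (Q_liver + fup*Clint_w/Rb2p) is the
    fraction surviving first-pass hepatic extraction.
    """
    prov: dict[str, str] = {}
    if chem.caco2_papp is not None:
        fabs = caco2_to_fabs(chem.caco2_papp, caco2_curve)
        prov["Fabs"] = f"caco2 curve (Papp={chem.caco2_papp:g})"
    else:
        fabs = 1.0
        prov["Fabs"] = "default (no Caco-2 measurement)"
    clint_gut = 0.01 * clint_w  # gut metabolism: 1% of hepatic intrinsic clearance
    prov["clint_gut"] = f"0.01 * Clint_w = {clint_gut:g} L/h"
    fgut = q_liver / (q_liver + fup * clint_gut)
    fhep = q_liver / (q_liver + fup * clint_w / rb2p)
    return fabs, fgut, fhep, prov


def _resolve_invitro(chem, species, options):
    """Common fup/Clint resolution with defaults and corrections."""
    default_to_human = options.get("default_to_human", True)
    fup_uv, fup_prov = get_field(chem, "fup", species, default_to_human)
    fup = fup_uv.point
    if fup == 0.0:
        if not options.get("allow_fup_default", True):
            raise MissingDataError(
                f"{chem.dtxsid}: fup measured as 0 and default substitution disabled"
            )
        fup = DEFAULT_FUP
        fup_prov += f"; assay failed, default {DEFAULT_FUP:g} substituted"
    if options.get("adjust_fup", True):
        fup = calc_fup_correction(fup, chem, enabled=True, config=options.get("partition_config"))
        fup_prov += "; lipid-corrected"
    clint_uv, clint_prov = get_field(chem, "Clint", species, default_to_human)
    return fup, fup_prov, clint_uv.point, clint_prov


PBTK_LUMPING = {
    "gut": ("gut",),
    "liver": ("liver",),
    "kidney": ("kidney",),
    "lung": ("lung",),
}


def parameterize_model(
    model: str,
    chem: ChemicalRecord,
    species: str = "Human",
    options: dict | None = None,
    lib: ChemicalLibrary | None = None,
) -> ParameterSet:
    """Build the full ParameterSet for a perfusion-limited model.

    options: default_to_human (True), adjust_fup (True), allow_fup_default
    (True), regression_calibrated (False), physiology_path, tissue_table,
    partition_config.
    """
    from .models import get_model  # late import to avoid cycle

    options = dict(options or {})
    info = get_model(model)
    phys = options.get("physiology") or load_physiology(species, options.get("physiology_path"))
    tissues = options.get("tissue_table") or load_tissue_table()
    pconfig = options.get("partition_config") or load_partition_config()

    fup, fup_prov, clint, clint_prov = _resolve_invitro(chem, species, options)
    fu_hep = calc_hep_fu(chem)

    if chem.logP is None and "logP" not in info.data_requirements.required_params:
        # steady-state-only models can run without partitioning data
        return _parameterize_slim(
            model, info, chem, species, phys, lib, fup, fup_prov, clint, clint_prov, fu_hep
        )

    kp = predict_partitioning_schmitt(
        chem, fup, tissues, calibrated=options.get("regression_calibrated", False), config=pconfig
    )
    rb2p, rb2p_prov = resolve_rblood2plasma(chem, species, lib, fup, phys.hct, tissues, pconfig)

    lumped_kp, lumped_vol, lumped_flow = lump_tissues(kp, tissues, info.lumping_scheme)

    BW = phys.BW
    scale = BW**ALLOMETRIC_EXPONENT
    qc = phys.QC * scale
    gfr = phys.GFR * scale
    clint_w = scale_clint_to_liver(clint / fu_hep, phys)
    q_liver_total = (lumped_flow.get("gut", 0.0) + lumped_flow.get("liver", 0.0)) * qc
    clh = calc_hep_clearance(clint, fup, phys, q_liver=q_liver_total, fu_hep=fu_hep)
    fabs, fgut, fhep, oral_prov = calc_oral_bioavailability(
        chem, fup, clint_w, q_liver_total, rb2p
    )

    p = ParameterSet(model=model, species=species)
    v, u = p.values, p.units

    def put(name, value, unit, prov=None):
        v[name] = float(value)
        u[name] = unit
        if prov:
            p.provenance[name] = prov

    put("BW", BW, "kg")
    put("MW", chem.MW, "g/mol")
    put("fup", fup, "unitless", fup_prov)
    put("Clint", clint, "uL/min/10^6 cells", clint_prov)
    put("Clint_w", clint_w, "L/h", f"scaled whole liver, fu_hep={fu_hep:.4g}")
    put("CLh", clh, "L/h", "well-stirred")
    put("Rblood2plasma", rb2p, "unitless", rb2p_prov)
    put("hematocrit", phys.hct, "unitless")
    put("Fabs", fabs, "unitless", oral_prov.get("Fabs"))
    put("Fgut", fgut, "unitless", oral_prov.get("clint_gut"))
    put("Fhep", fhep, "unitless")
    put("ka", DEFAULT_KA_PER_H, "1/h")
    put("Qcardiac", qc, "L/h")
    put("GFR", gfr, "L/h")
    for comp in ("gut", "liver", "kidney", "lung", "rest"):
        if comp in lumped_kp:
            put(f"K{comp}2pu", lumped_kp[comp], "unitless")
            put(f"V{comp}", lumped_vol[comp] * BW, "L")
            qname = f"Q{comp}"
            if comp == "lung":
                put(qname, qc, "L/h")  # lung sees total cardiac output
            elif comp == "rest":
                explicit = sum(
                    lumped_flow.get(c, 0.0) for c in ("gut", "liver", "kidney")
                )
                put(qname, (1.0 - explicit) * qc, "L/h")
            else:
                put(qname, lumped_flow[comp] * qc, "L/h")
    put("Krbc2pu", kp["red blood cells"], "unitless")
    put("Vart", phys.Vart_frac * BW, "L")
    put("Vven", phys.Vven_frac * BW, "L")

    if model == "gas_pbtk":
        _extend_gas(p, chem, phys, rb2p, fup, options)
    if model == "1compartment":
        _extend_one_compartment(p)

    _check_contract(p, info)
    return p


def _parameterize_slim(
    model, info, chem, species, phys, lib, fup, fup_prov, clint, clint_prov, fu_hep
) -> ParameterSet:
    """Minimal parameter set (no tissue partitioning) for SS-only models."""
    clint_w = scale_clint_to_liver(clint / fu_hep, phys)
    q_liver = total_liver_flow(phys)
    clh = calc_hep_clearance(clint, fup, phys, q_liver=q_liver, fu_hep=fu_hep)
    try:
        rb2p, rb2p_prov = resolve_rblood2plasma(chem, species, lib, None, phys.hct)
    except ValueError:
        rb2p, rb2p_prov = 1.0, "default(1.0)"
    p = ParameterSet(model=model, species=species)
    scale = phys.BW**ALLOMETRIC_EXPONENT
    p.values = {
        "BW": phys.BW, "MW": chem.MW, "fup": fup, "Clint": clint,
        "Clint_w": clint_w, "CLh": clh, "GFR": phys.GFR * scale,
        "Rblood2plasma": rb2p,
    }
    p.units = {
        "BW": "kg", "MW": "g/mol", "fup": "unitless",
        "Clint": "uL/min/10^6 cells", "Clint_w": "L/h", "CLh": "L/h",
        "GFR": "L/h", "Rblood2plasma": "unitless",
    }
    p.provenance = {"fup": fup_prov, "Clint": clint_prov, "Rblood2plasma": rb2p_prov}
    _check_contract(p, info)
    return p


def _extend_gas(p: ParameterSet, chem: ChemicalRecord, phys: PhysiologyTable,
                rb2p: float, fup: float, options: dict) -> None:
    if chem.logHenry is None:
        raise MissingDataError(
            f"{chem.dtxsid}: log Henry's law constant required for the gas model"
        )
    hlc = 10.0 ** chem.logHenry  # atm·m³/mol
    T = phys.body_temperature
    r_m3 = R_L_ATM * 1e-3  # m³·atm·mol⁻¹·K⁻¹
    kwater2air = hlc / (r_m3 * T)
    kblood2water = rb2p / fup  # blood:water via unbound-plasma ~ water
    kblood2air = kblood2water / kwater2air
    if kblood2air > 1e8:
        warnings.warn(
            f"{chem.dtxsid}: Kblood2air = {kblood2air:.3g} (essentially non-volatile); "
            "gas-exchange terms are negligible and the chemical is out of the "
            "gas model's intended domain",
            stacklevel=3,
        )
    v, u = p.values, p.units
    v["Qalv"] = phys.Qalv * phys.BW**ALLOMETRIC_EXPONENT
    u["Qalv"] = "L/h"
    v["Kwater2air"] = kwater2air
    u["Kwater2air"] = "unitless"
    v["Kblood2air"] = kblood2air
    u["Kblood2air"] = "unitless"
    v["kdes"] = options.get("mucus_desorption_per_h", 1.0)
    u["kdes"] = "1/h"
    v["fdep"] = options.get("mucus_deposition_fraction", 0.01)
    u["fdep"] = "unitless"


def _extend_one_compartment(p: ParameterSet) -> None:
    """Collapse the PBTK parameterization to Vdist and kelim."""
    v, u = p.values, p.units
    fup, rb2p = v["fup"], v["Rblood2plasma"]
    vdist = v["Vven"] + v["Vart"]
    for comp in ("gut", "liver", "kidney", "lung", "rest"):
        vdist += v[f"V{comp}"] * v[f"K{comp}2pu"] * fup
    # plasma-referenced distribution volume and total plasma clearance
    cl_tot = v["CLh"] + fup * v["GFR"]
    v["Vdist"] = vdist
    u["Vdist"] = "L"
    v["kelim"] = cl_tot / vdist
    u["kelim"] = "1/h"


def _check_contract(p: ParameterSet, info) -> None:
    expected = set(info.param_names)
    have = set(p.values)
    missing = expected - have
    if missing:
        raise ValueError(f"{p.model}: parameterization missing {sorted(missing)}")
    # drop anything the model does not declare so the set matches exactly
    for extra in sorted(have - expected):
        del p.values[extra]
        del p.units[extra]
    bad = [k for k, val in p.values.items() if not np.isfinite(val)]
    if bad:
        raise ValueError(f"{p.model}: non-finite parameters {bad}")


def parameterize_gas_model(
    chem: ChemicalRecord,
    species: str = "Human",
    options: dict | None = None,
    lib: ChemicalLibrary | None = None,
) -> ParameterSet:
    """Parameterize the gas-inhalation PBTK model (adds blood:air partition)."""
    return parameterize_model("gas_pbtk", chem, species, options, lib)
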