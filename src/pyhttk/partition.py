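"""Tissue:plasma partition coefficients by a component-based (Schmitt-type)
equilibrium model, plus ionization, the in vitro/in vivo fup correction, the
blood:plasma ratio decision cascade, and tissue lumping.

Each tissue is treated as a mixture of water, neutral lipid, phospholipid
membrane, and protein.  The chemical's affinity for each component is
predicted from logP and its ionization state at the tissue pH
(Henderson-Hasselbalch); protein affinity is inferred from the plasma
unbound fraction.  The predicted Kp is the tissue:*unbound*-plasma
concentration ratio.  An optional per-tissue affine calibration in log10
space (default: identity) can be layered on top.

Constants live in ``data/schmitt_calibration.yaml`` and are overridable.
"""

from __future__ import annotations

import importlib.resources as _res
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .chem import ChemicalLibrary, ChemicalRecord

__all__ = [
    "TissueComposition",
    "PartitionSet",
    "LumpingScheme",
    "load_tissue_table",
    "load_partition_config",
    "ionization_fractions",
    "ionized_octanol_water",
    "predict_partitioning_schmitt",
    "calc_fup_correction",
    "resolve_rblood2plasma",
    "lump_tissues",
]


@dataclass(frozen=True)
class TissueComposition:
    tissue: str
    f_water: float
    f_neutral_lipid: float
    f_phospholipid: float
    f_protein: float
    pH: float
    vol_frac_BW: float  # L per kg body weight
    flow_frac_QC: float  # fraction of cardiac output

    def __post_init__(self) -> None:
        for f in (self.f_water, self.f_neutral_lipid, self.f_phospholipid, self.f_protein):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"{self.tissue}: composition fraction outside [0,1]")
        if self.vol_frac_BW < 0:
            raise ValueError(f"{self.tissue}: vol_frac_BW must be >= 0")


#: tissue name -> Kp (tissue : unbound plasma), all > 0
PartitionSet = dict


@dataclass(frozen=True)
class LumpingScheme:
    """Assignment of tissues to lumped model compartments.

    Tissues not listed in any lump are pooled into ``remainder``.
    """

    lumps: dict[str, tuple[str, ...]]
    remainder: str = "rest"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for members in self.lumps.values():
            for t in members:
                if t in seen:
                    raise ValueError(f"tissue {t!r} assigned to more than one lump")
                seen.add(t)


def load_tissue_table(path=None) -> list[TissueComposition]:
    """Load the tissue composition table (packaged default or a user CSV)."""
    if path is None:
        path = _res.files("pyhttk.data") / "tissue_composition.csv"
    df = pd.read_csv(path)
    return [TissueComposition(**row) for row in df.to_dict("records")]


def load_partition_config(path=None) -> dict:
    """Load component-model constants and per-tissue calibration."""
    if path is None:
        path = _res.files("pyhttk.data") / "schmitt_calibration.yaml"
    with open(path) as fh:
        return yaml.safe_load(fh)


def ionization_fractions(
    pH: float,
    pKa_donor: tuple[float, ...] = (),
    pKa_accept: tuple[float, ...] = (),
) -> tuple[float, float, float, float]:
    """Henderson-Hasselbalch equilibrium fractions at a given pH.

    Returns (f_neutral, f_anion, f_cation, f_zwitterion).  Acidic (proton
    donor) and basic (proton acceptor) sites are treated as independent
    equilibria; a species with at least one deprotonated acid *and* one
    protonated base counts as zwitterionic.  Empty pKa lists give a fully
    neutral chemical.
    """
    if not (0.0 < pH < 14.0):
        raise ValueError(f"pH must lie in (0, 14), got {pH}")
    # P(no acid site deprotonated), P(no base site protonated)
    p_acid_neutral = 1.0
    for pka in pKa_donor:
        p_acid_neutral *= 1.0 / (1.0 + 10.0 ** (pH - pka))
    p_base_neutral = 1.0
    for pka in pKa_accept:
        p_base_neutral *= 1.0 / (1.0 + 10.0 ** (pka - pH))
    f_neutral = p_acid_neutral * p_base_neutral
    f_anion = (1.0 - p_acid_neutral) * p_base_neutral
    f_cation = p_acid_neutral * (1.0 - p_base_neutral)
    f_zwitter = (1.0 - p_acid_neutral) * (1.0 - p_base_neutral)
    return (f_neutral, f_anion, f_cation, f_zwitter)


def ionized_octanol_water(logP: float, f_neutral: float, config: dict | None = None) -> float:
    """Effective octanol:water distribution (Dow) of the neutral/ionized mix."""
    cfg = (config or load_partition_config())["constants"]
    p_neutral = 10.0 ** logP
    p_ion = 10.0 ** (logP + cfg["log_d_ion_offset"])
    return f_neutral * p_neutral + (1.0 - f_neutral) * p_ion


def predict_partitioning_schmitt(
    chem: ChemicalRecord,
    fup: float,
    tissues: list[TissueComposition] | None = None,
    calibrated: bool = False,
    config: dict | None = None,
) -> PartitionSet:
    """Predict tissue:unbound-plasma partition coefficients.

    Per tissue the Kp is a composition-weighted sum of component
    affinities, ionization-corrected at the tissue pH:

        Kp = f_water + f_nl * K_nl + f_pl * K_pl + f_protein * K_prot

    K_nl is the octanol:water distribution of the species mix; K_pl a
    membrane-affinity regression on logP with per-charge-state factors;
    K_prot is inferred from the plasma unbound fraction (protein binding in
    tissue interstitium scales with binding to plasma protein).  With
    ``calibrated=True`` a per-tissue affine log10 adjustment from the
    config is applied (defaults to identity).
    """
    if not (0.0 < fup <= 1.0):
        raise ValueError(
            f"fup must lie in (0, 1]; got {fup}. A fup recorded as 0 must go "
            "through the default-substitution path before partitioning."
        )
    if chem.logP is None:
        raise ValueError(f"{chem.dtxsid}: logP required for partitioning")
    tissues = tissues if tissues is not None else load_tissue_table()
    config = config or load_partition_config()
    cfg = config["constants"]

    # chemical affinity for protein, inferred from plasma binding:
    # (1-fup)/fup bound:free in plasma, scaled by plasma protein content
    k_protein = ((1.0 - fup) / fup) / cfg["plasma_protein_fraction"]

    kp: PartitionSet = {}
    for t in tissues:
        f_n, f_a, f_c, f_z = ionization_fractions(t.pH, chem.pKa_donor, chem.pKa_accept)
        k_nl = ionized_octanol_water(chem.logP, f_n, config)
        ma_neutral = 10.0 ** (
            cfg["membrane_affinity_slope"] * chem.logP + cfg["membrane_affinity_intercept"]
        )
        k_pl = ma_neutral * (
            f_n
            + f_c * cfg["membrane_factor_cation"]
            + f_a * cfg["membrane_factor_anion"]
            + f_z * cfg["membrane_factor_zwitterion"]
        )
        raw = (
            t.f_water
            + t.f_neutral_lipid * k_nl
            + t.f_phospholipid * k_pl
            + t.f_protein * k_protein
        )
        if calibrated:
            cal = config.get("tissues", {}).get(t.tissue, config.get("default", {}))
            slope = cal.get("slope", 1.0)
            intercept = cal.get("intercept", 0.0)
            raw = 10.0 ** (slope * np.log10(raw) + intercept)
        kp[t.tissue] = float(raw)
    return kp


def calc_fup_correction(
    fup_measured: float,
    chem: ChemicalRecord,
    enabled: bool = True,
    config: dict | None = None,
    plasma_pH: float = 7.4,
) -> float:
    """Correct the measured fup for in vitro vs in vivo lipid differences.

    The in vitro binding assay under-represents plasma lipid, so lipophilic
    chemicals appear freer than they are in vivo.  The corrected value
    accounts for distribution into plasma lipid:

        fup_corr = fup / (1 + Dow * f_lipid_plasma * fup)

    which tends to the identity for hydrophilic chemicals and strictly
    lowers fup as lipophilicity grows.  ``enabled=False`` is the identity.
    """
    if not (0.0 < fup_measured <= 1.0):
        raise ValueError("fup_measured must lie in (0, 1]")
    if not enabled or chem.logP is None:
        return fup_measured
    config = config or load_partition_config()
    f_n, *_ = ionization_fractions(plasma_pH, chem.pKa_donor, chem.pKa_accept)
    dow = ionized_octanol_water(chem.logP, f_n, config)
    f_lip = config["constants"]["plasma_lipid_fraction"]
    return fup_measured / (1.0 + dow * f_lip * fup_measured)


def resolve_rblood2plasma(
    chem: ChemicalRecord,
    species: str,
    lib: ChemicalLibrary | None,
    fup: float | None,
    hct: float,
    tissues: list[TissueComposition] | None = None,
    config: dict | None = None,
) -> tuple[float, str]:
    """Blood:plasma concentration ratio via the decision cascade.

    1. species-specific measured value; 2. measured human value;
    3. computed as ``(1 - hct) + hct * Krbc2pu * fup`` with the red blood
    cell Kp from the component partition model; 4. the mean of measured
    values across the library.  Returns (Rb2p, provenance).
    """
    if not (0.0 <= hct < 1.0):
        raise ValueError("hematocrit must lie in [0, 1)")
    if species in chem.Rblood2plasma_measured:
        return chem.Rblood2plasma_measured[species], "measured_species"
    if "Human" in chem.Rblood2plasma_measured:
        return chem.Rblood2plasma_measured["Human"], "measured_human"
    if chem.logP is not None and fup is not None and fup > 0:
        kp = predict_partitioning_schmitt(chem, fup, tissues, config=config)
        krbc2pu = kp["red blood cells"]
        return (1.0 - hct) + hct * krbc2pu * fup, "schmitt_computed"
    if lib is not None:
        measured = [
            v
            for rec in lib.records.values()
            for v in rec.Rblood2plasma_measured.values()
        ]
        if measured:
            return float(np.mean(measured)), "library_average"
    raise ValueError(
        f"{chem.dtxsid}: no measured Rblood2plasma, insufficient data to "
        "compute one, and no library average available"
    )


def lump_tissues(
    kp: PartitionSet,
    tissues: list[TissueComposition],
    scheme: LumpingScheme,
) -> tuple[dict, dict, dict]:
    """Aggregate tissues into lumped compartments.

    Lumped volume and flow are sums over members; the lumped Kp is the
    volume-weighted mean of member Kp, which conserves sum(V*Kp) exactly.
    Tissues absent from every lump are pooled into the scheme's remainder
    compartment.  Red blood cells (zero volume/flow) never lump.
    """
    by_name = {t.tissue: t for t in tissues}
    assigned: set[str] = set()
    lumps = {name: list(members) for name, members in scheme.lumps.items()}
    for members in lumps.values():
        for t in members:
            if t not in by_name:
                raise ValueError(f"lumping scheme names unknown tissue {t!r}")
            assigned.add(t)
    rest = [
        t.tissue
        for t in tissues
        if t.tissue not in assigned and t.vol_frac_BW > 0
    ]
    if rest:
        lumps.setdefault(scheme.remainder, [])
        lumps[scheme.remainder].extend(rest)

    lumped_kp: dict[str, float] = {}
    lumped_vol: dict[str, float] = {}
    lumped_flow: dict[str, float] = {}
    for name, members in lumps.items():
        if not members:
            continue
        v = sum(by_name[m].vol_frac_BW for m in members)
        q = sum(by_name[m].flow_frac_QC for m in members)
        vkp = sum(by_name[m].vol_frac_BW * kp[m] for m in members)
        lumped_vol[name] = v
        lumped_flow[name] = q
        lumped_kp[name] = vkp / v if v > 0 else float(np.mean([kp[m] for m in members]))
    return lumped_kp, lumped_vol, lumped_flow
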