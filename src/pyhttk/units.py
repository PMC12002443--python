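"""Centralized unit conversion and body-weight dose scaling.

Unit conversion errors are historically the single worst bug class in
toxicokinetic software, so every conversion in the package goes through
:func:`convert_units` (a closed, controlled vocabulary) or
:func:`scale_dosing` (body-weight scaling of "/kg" units).  There is
deliberately no free-form unit parser.

Amount units are mass (mg) or moles (umol); concentration units are mg/L,
uM (micromolar) and, for gas-phase compartments, ppmv (parts per million by
volume).  ppmv <-> molar conversions use the ideal gas law at the context
temperature (default 298.15 K ambient; the blood:air partition coefficient
uses body temperature from the physiology table instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "Quantity",
    "UnitContext",
    "UnitError",
    "convert_units",
    "scale_dosing",
    "conversion_table",
    "R_L_ATM",
]

#: Ideal gas constant in L·atm·mol⁻¹·K⁻¹.
R_L_ATM = 0.082057

#: Units convert_units knows how to interconvert.
CONVERTIBLE_VOCABULARY = frozenset(
    {
        "mg",
        "umol",
        "mg/L",
        "uM",
        "ppmv",
        "mg/kg",
        "mg/kg/day",
        "mg/day",
        "umol/day",
        "mg/L/day",
        "uM/day",
        "L",
        "kg",
    }
)

#: Additional descriptive units a ParameterSet may declare.  These pass the
#: dimensional audit but have no conversion path (they never cross a model
#: boundary as data).
DESCRIPTIVE_VOCABULARY = frozenset(
    {
        "unitless",
        "g/mol",
        "K",
        "L/h",
        "L/day",
        "1/h",
        "1/day",
        "uL/min/10^6 cells",
        "uM*day",
        "L/kg",
    }
)

VOCABULARY = CONVERTIBLE_VOCABULARY | DESCRIPTIVE_VOCABULARY


class UnitError(ValueError):
    """A conversion was requested that has no path or lacks context."""


@dataclass(frozen=True)
class Quantity:
    """A value tagged with a unit from the controlled vocabulary."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VOCABULARY:
            raise UnitError(
                f"unit {self.unit!r} is not in the controlled vocabulary"
            )


@dataclass(frozen=True)
class UnitContext:
    """Chemical/physical context needed by some conversions.

    volume is required for amount <-> concentration; state must be "gas"
    for ppmv; temperature applies to ideal-gas conversions only.
    """

    MW: float
    volume: float | None = None
    temperature: float = 298.15
    state: str = field(default="liquid")

    def __post_init__(self) -> None:
        if not self.MW > 0:
            raise ValueError("MW must be > 0")
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0")


def _parse(unit: str) -> tuple[str, bool, bool]:
    """Split a vocabulary unit into (base, per_kg, per_day)."""
    per_day = unit.endswith("/day")
    if per_day:
        unit = unit[: -len("/day")]
    per_kg = unit.endswith("/kg")
    if per_kg:
        unit = unit[: -len("/kg")]
    return unit, per_kg, per_day


def _molar_density_uM_per_ppmv(temperature: float) -> float:
    """uM of ideal gas per ppmv of mixing ratio: n/V = P/(RT), P = 1e-6 atm."""
    return 1e-6 / (R_L_ATM * temperature) * 1e6


def _base_convert(value: float, src: str, dst: str, ctx: UnitContext) -> float:
    """Convert between base units (no /kg, no /day)."""
    if src == dst:
        return value
    MW = ctx.MW

    # normalise everything onto a per-dimension hub: umol (amount), uM (conc)
    def need_volume() -> float:
        if ctx.volume is None:
            raise UnitError(
                f"conversion {src} -> {dst} requires a volume in the "
                "UnitContext (amount <-> concentration)"
            )
        return ctx.volume

    def need_gas() -> None:
        if ctx.state != "gas":
            raise UnitError(
                f"conversion involving ppmv ({src} -> {dst}) requires a "
                "gas-state UnitContext"
            )

    amount_units = {"mg", "umol"}
    conc_units = {"mg/L", "uM", "ppmv"}

    if src in amount_units:
        umol = value if src == "umol" else value * 1000.0 / MW
        if dst in amount_units:
            return umol if dst == "umol" else umol * MW / 1000.0
        if dst in conc_units:
            uM = umol / need_volume()
            return _from_uM(uM, dst, ctx, need_gas)
        raise UnitError(f"no conversion path from {src} to {dst}")
    if src in conc_units:
        if src == "ppmv":
            need_gas()
        uM = {
            "uM": value,
            "mg/L": value * 1000.0 / MW,
            "ppmv": value * _molar_density_uM_per_ppmv(ctx.temperature)
            if src == "ppmv"
            else None,
        }[src]
        if dst in conc_units:
            return _from_uM(uM, dst, ctx, need_gas)
        if dst in amount_units:
            umol = uM * need_volume()
            return umol if dst == "umol" else umol * MW / 1000.0
        raise UnitError(f"no conversion path from {src} to {dst}")
    raise UnitError(f"no conversion path from {src} to {dst}")


def _from_uM(uM: float, dst: str, ctx: UnitContext, need_gas) -> float:
    if dst == "uM":
        return uM
    if dst == "mg/L":
        return uM * ctx.MW / 1000.0
    if dst == "ppmv":
        need_gas()
        return uM / _molar_density_uM_per_ppmv(ctx.temperature)
    raise UnitError(f"no conversion path to {dst}")


def convert_units(q: Quantity, to: str, ctx: UnitContext) -> Quantity:
    """Convert a Quantity to another unit in the controlled vocabulary.

    mg/L -> uM multiplies by 1000/MW; ppmv conversions use the ideal-gas
    molar density at ``ctx.temperature`` and require ``ctx.state == "gas"``;
    amount <-> concentration requires ``ctx.volume``.  Per-body-weight
    ("/kg") units cannot be converted here — apply :func:`scale_dosing`
    first.  All conversions are exact and invertible.
    """
    if to not in VOCABULARY:
        raise UnitError(f"unit {to!r} is not in the controlled vocabulary")
    if q.unit in DESCRIPTIVE_VOCABULARY or to in DESCRIPTIVE_VOCABULARY:
        if q.unit == to:
            return q
        raise UnitError(f"{q.unit!r} -> {to!r}: descriptive units have no conversion path")
    src_base, src_kg, src_day = _parse(q.unit)
    dst_base, dst_kg, dst_day = _parse(to)
    if src_kg != dst_kg:
        raise UnitError(
            f"cannot convert {q.unit} -> {to}: per-body-weight mismatch; "
            "use scale_dosing to remove '/kg' first"
        )
    if src_day != dst_day:
        raise UnitError(
            f"cannot convert {q.unit} -> {to}: per-day rate mismatch"
        )
    return Quantity(_base_convert(q.value, src_base, dst_base, ctx), to)


def scale_dosing(dose: Quantity, BW: float) -> Quantity:
    """Scale a per-body-weight dose to an absolute dose.

    Detects "/kg" in the unit string, multiplies the value by the body
    weight (kg) and removes "/kg" from the unit.  A unit without "/kg" is
    returned unchanged with a warning (no-op).
    """
    if "/kg" not in dose.unit:
        warnings.warn(
            f"scale_dosing: unit {dose.unit!r} has no '/kg'; returning dose unchanged",
            stacklevel=2,
        )
        return dose
    new_unit = dose.unit.replace("/kg", "", 1)
    return Quantity(dose.value * BW, new_unit)


def conversion_table(MW: float = 100.0, temperature: float = 298.15) -> list[dict]:
    """Enumerate the supported base conversions for audit (CLI `units table`)."""
    ctx = UnitContext(MW=MW, volume=1.0, temperature=temperature, state="gas")
    rows = []
    bases = ["mg", "umol", "mg/L", "uM", "ppmv"]
    for src in bases:
        for dst in bases:
            if src == dst:
                continue
            factor = _base_convert(1.0, src, dst, ctx)
            rows.append(
                {"from": src, "to": dst, "factor_at_MW": factor, "MW": MW, "T": temperature}
            )
    return rows
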