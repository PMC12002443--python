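"""Chemical data model: loading, merging, eligibility filtering, and a
synthetic-library generator.

The central container is :class:`ChemicalLibrary`, a keyed collection of
per-chemical physico-chemical properties and in vitro toxicokinetic
measurements (wide one-row-per-chemical semantics, species-specific columns
suffixed ``.Human`` / ``.Rat`` in the canonical CSV dialect).

In vitro values may carry Bayesian uncertainty encoded as comma-separated
tuple strings: intrinsic hepatic clearance (Clint) as a 4-tuple
``median,l95,u95,p_no_effect`` and fraction unbound in plasma (fup) as a
3-tuple ``median,l95,u95``.  A fup recorded as exactly 0 means the binding
assay was attempted but failed (highly bound chemical); substitution by the
0.5% default happens at parameterization, never in the library.
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "UncertainValue",
    "ChemicalRecord",
    "ChemicalLibrary",
    "DataRequirements",
    "parse_uncertainty_tuple",
    "format_uncertainty_tuple",
    "load_library",
    "write_library",
    "add_chemtable",
    "get_cheminfo",
    "get_param",
    "generate_synthetic_library",
    "MissingDataError",
    "SchemaError",
]

#: Default fraction unbound substituted downstream for failed (0) assays.
DEFAULT_FUP = 0.005

#: Default volatility cutoff, log10(atm·m³/mol).  Chemicals with logHenry
#: strictly greater are "volatile" and excluded from liquid-only models.
DEFAULT_LOG_HENRY_THRESHOLD = -4.5

SPECIES_FIELDS = ("Clint", "fup", "Rblood2plasma")


class SchemaError(ValueError):
    """A CSV is missing a mandatory column or has an unusable row."""


class MissingDataError(KeyError):
    """A requested chemical/field combination is absent."""


@dataclass(frozen=True)
class UncertainValue:
    """A central estimate with optional Bayesian 95% bounds.

    For clearance the 4th element, ``p_no_effect``, is the posterior
    probability that no systematic clearance was observed.
    """

    point: float
    l95: float | None = None
    u95: float | None = None
    p_no_effect: float | None = None

    def __post_init__(self) -> None:
        if (self.l95 is None) != (self.u95 is None):
            raise ValueError("l95 and u95 must be given together")
        if self.l95 is not None and not (self.l95 <= self.point <= self.u95):
            raise ValueError(
                f"require l95 <= point <= u95, got ({self.l95}, {self.point}, {self.u95})"
            )
        if self.p_no_effect is not None and not (0.0 <= self.p_no_effect <= 1.0):
            raise ValueError("p_no_effect must lie in [0, 1]")

    @property
    def has_bounds(self) -> bool:
        return self.l95 is not None


def parse_uncertainty_tuple(s: str | float, kind: str) -> UncertainValue:
    """Parse a 1-, 3- (fup) or 4- (clint) tuple string into an UncertainValue.

    Ordering is median first, then lower and upper 95th percentiles, then
    (clint only) the probability of no clearance.
    """
    if kind not in ("clint", "fup"):
        raise ValueError(f"kind must be 'clint' or 'fup', got {kind!r}")
    if isinstance(s, (int, float)) and not isinstance(s, bool):
        parts = [float(s)]
    else:
        try:
            parts = [float(p) for p in str(s).split(",")]
        except ValueError as exc:
            raise ValueError(f"non-numeric element in tuple string {s!r}") from exc
    if len(parts) == 1:
        uv = UncertainValue(parts[0])
    elif len(parts) == 3 and kind == "fup":
        uv = UncertainValue(parts[0], parts[1], parts[2])
    elif len(parts) == 4 and kind == "clint":
        uv = UncertainValue(parts[0], parts[1], parts[2], parts[3])
    else:
        raise ValueError(
            f"{kind} tuple must have 1, {'3' if kind == 'fup' else '4'} elements, "
            f"got {len(parts)}: {s!r}"
        )
    if kind == "fup" and not (0.0 <= uv.point <= 1.0):
        raise ValueError(f"fup must lie in [0, 1], got {uv.point}")
    if kind == "clint" and uv.point < 0:
        raise ValueError(f"Clint must be >= 0, got {uv.point}")
    return uv


def format_uncertainty_tuple(uv: UncertainValue) -> str:
    """Inverse of :func:`parse_uncertainty_tuple` (round-trip exact)."""
    parts = [uv.point]
    if uv.has_bounds:
        parts += [uv.l95, uv.u95]
    if uv.p_no_effect is not None:
        parts.append(uv.p_no_effect)
    return ",".join(repr(float(p)) for p in parts)


@dataclass
class ChemicalRecord:
    """Per-chemical physico-chemical and in vitro data with provenance.

    Species-specific fields (Clint, fup, Rblood2plasma_measured) are dicts
    keyed by species name ("Human", "Rat", ...).
    """

    dtxsid: str
    casrn: str = ""
    name: str = ""
    MW: float = float("nan")
    logP: float | None = None
    pKa_donor: tuple[float, ...] = ()
    pKa_accept: tuple[float, ...] = ()
    logHenry: float | None = None
    Clint: dict[str, UncertainValue] = field(default_factory=dict)
    fup: dict[str, UncertainValue] = field(default_factory=dict)
    Rblood2plasma_measured: dict[str, float] = field(default_factory=dict)
    caco2_papp: float | None = None  # 1e-6 cm/s
    chem_class: frozenset[str] = frozenset()
    references: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not (self.MW > 0):
            raise ValueError(f"{self.dtxsid}: MW must be > 0, got {self.MW}")
        for sp, uv in self.fup.items():
            if not (0.0 <= uv.point <= 1.0):
                raise ValueError(f"{self.dtxsid}: fup[{sp}] outside [0, 1]")
        for sp, uv in self.Clint.items():
            if uv.point < 0:
                raise ValueError(f"{self.dtxsid}: Clint[{sp}] < 0")
        if self.caco2_papp is not None and self.caco2_papp < 0:
            raise ValueError(f"{self.dtxsid}: caco2_papp < 0")

    def has_field(self, name: str, species: str, default_to_human: bool = True) -> bool:
        try:
            get_field(self, name, species, default_to_human)
            return True
        except MissingDataError:
            return False


def get_field(rec: ChemicalRecord, name: str, species: str, default_to_human: bool = True):
    """Resolve a (possibly species-specific) field, returning (value, provenance)."""
    if name in SPECIES_FIELDS:
        attr = "Rblood2plasma_measured" if name == "Rblood2plasma" else name
        table = getattr(rec, attr)
        if species in table:
            return table[species], species.lower()
        if default_to_human and "Human" in table:
            return table["Human"], "human-default"
        raise MissingDataError(
            f"chemical {rec.dtxsid}: no {name} for species {species!r}"
            + ("" if default_to_human else " (default_to_human disabled)")
        )
    value = getattr(rec, name, None)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise MissingDataError(f"chemical {rec.dtxsid}: field {name!r} absent")
    return value, "chemical"


@dataclass
class ChemicalLibrary:
    """Keyed collection of ChemicalRecord with creation metadata."""

    records: dict[str, ChemicalRecord] = field(default_factory=dict)
    timestamp: str = field(default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds"))
    sources: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, dtxsid: str) -> bool:
        return dtxsid in self.records

    def __getitem__(self, key: str) -> ChemicalRecord:
        rec = self.lookup(key)
        if rec is None:
            raise MissingDataError(f"chemical {key!r} not in library")
        return rec

    def lookup(self, key: str) -> ChemicalRecord | None:
        """dtxsid primary key; casrn and name are secondary aliases."""
        if key in self.records:
            return self.records[key]
        for rec in self.records.values():
            if key and (rec.casrn == key or rec.name == key):
                return rec
        return None

    def add(self, rec: ChemicalRecord) -> None:
        rec.validate()
        self.records[rec.dtxsid] = rec

    def ids(self) -> list[str]:
        return list(self.records)


@dataclass(frozen=True)
class DataRequirements:
    """Per-model data inclusion/exclusion criteria."""

    required_params: tuple[str, ...]
    exclude_fup_zero: bool = False
    log_henry_threshold: float | None = None
    chem_class_filter: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.required_params:
            raise ValueError("required_params must be non-empty")


# ---------------------------------------------------------------------------
# CSV I/O — canonical wide dialect

CANONICAL_COLUMNS = {
    "dtxsid": "DTXSID",
    "casrn": "CASRN",
    "name": "Name",
    "MW": "MW",
    "logP": "logP",
    "pKa_donor": "pKa_Donor",
    "pKa_accept": "pKa_Accept",
    "logHenry": "logHenry",
    "caco2_papp": "Caco2.Pab",
    "chem_class": "Chemical.Class",
}


def _load_dialect(dialect) -> dict[str, str]:
    mapping = dict(CANONICAL_COLUMNS)
    if dialect is None:
        return mapping
    if isinstance(dialect, (str,)):
        with open(dialect) as fh:
            overrides = yaml.safe_load(fh) or {}
    else:
        overrides = dict(dialect)
    unknown = set(overrides) - set(mapping)
    if unknown:
        raise SchemaError(f"dialect maps unknown fields: {sorted(unknown)}")
    mapping.update(overrides)
    return mapping


def _split_list(cell) -> tuple[float, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        return ()
    return tuple(float(p) for p in str(cell).replace(";", ",").split(",") if p.strip())


def load_library(path, dialect=None) -> ChemicalLibrary:
    """Load a chemical library from a wide CSV (one row per chemical).

    Species-specific in vitro columns are suffixed ``.<Species>``
    (e.g. ``Clint.Human``).  Tuple-encoded strings are parsed via
    :func:`parse_uncertainty_tuple`.  Missing optional fields are left
    absent, never imputed at load time.
    """
    mapping = _load_dialect(dialect)
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    for mandatory in ("dtxsid", "MW"):
        if mapping[mandatory] not in df.columns:
            raise SchemaError(f"missing mandatory column {mapping[mandatory]!r}")
    lib = ChemicalLibrary(sources=(str(path),))
    for i, row in df.iterrows():
        def cell(field_name):
            col = mapping[field_name]
            if col not in df.columns:
                return None
            v = row[col]
            if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
                return None
            return v

        raw_mw = cell("MW")
        try:
            mw = float(raw_mw) if raw_mw is not None else float("nan")
        except ValueError:
            raise SchemaError(f"row {i + 2}: non-numeric MW {raw_mw!r}") from None
        rec = ChemicalRecord(
            dtxsid=str(cell("dtxsid")),
            casrn=str(cell("casrn") or ""),
            name=str(cell("name") or ""),
            MW=mw,
            logP=float(cell("logP")) if cell("logP") is not None else None,
            pKa_donor=_split_list(cell("pKa_donor")),
            pKa_accept=_split_list(cell("pKa_accept")),
            logHenry=float(cell("logHenry")) if cell("logHenry") is not None else None,
            caco2_papp=float(cell("caco2_papp")) if cell("caco2_papp") is not None else None,
            chem_class=frozenset(
                t.strip() for t in str(cell("chem_class") or "").split(";") if t.strip()
            ),
        )
        for col in df.columns:
            for fld, kind in (("Clint", "clint"), ("fup", "fup")):
                if col.startswith(fld + "."):
                    species = col.split(".", 1)[1]
                    v = row[col]
                    if v is not None and not (isinstance(v, float) and np.isnan(v)) and str(v).strip():
                        try:
                            getattr(rec, fld)[species] = parse_uncertainty_tuple(v, kind)
                        except ValueError as exc:
                            raise SchemaError(f"row {i + 2}, column {col}: {exc}") from None
            if col.startswith("Rblood2plasma."):
                species = col.split(".", 1)[1]
                v = row[col]
                if v is not None and not (isinstance(v, float) and np.isnan(v)) and str(v).strip():
                    rec.Rblood2plasma_measured[species] = float(v)
        if rec.dtxsid in lib.records:
            raise SchemaError(f"row {i + 2}: duplicate id {rec.dtxsid}")
        lib.add(rec)
    return lib


def write_library(lib: ChemicalLibrary, path) -> None:
    """Write a library in the canonical dialect (round-trips with load_library)."""
    species = sorted(
        {sp for rec in lib.records.values() for sp in (*rec.Clint, *rec.fup, *rec.Rblood2plasma_measured)}
    )
    rows = []
    for rec in lib.records.values():
        row = {
            "DTXSID": rec.dtxsid,
            "CASRN": rec.casrn,
            "Name": rec.name,
            "MW": repr(rec.MW),
            "logP": repr(rec.logP) if rec.logP is not None else "",
            "pKa_Donor": ";".join(repr(p) for p in rec.pKa_donor),
            "pKa_Accept": ";".join(repr(p) for p in rec.pKa_accept),
            "logHenry": repr(rec.logHenry) if rec.logHenry is not None else "",
            "Caco2.Pab": repr(rec.caco2_papp) if rec.caco2_papp is not None else "",
            "Chemical.Class": ";".join(sorted(rec.chem_class)),
        }
        for sp in species:
            if sp in rec.Clint:
                row[f"Clint.{sp}"] = format_uncertainty_tuple(rec.Clint[sp])
            if sp in rec.fup:
                row[f"fup.{sp}"] = format_uncertainty_tuple(rec.fup[sp])
            if sp in rec.Rblood2plasma_measured:
                row[f"Rblood2plasma.{sp}"] = repr(rec.Rblood2plasma_measured[sp])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# merge / query

def add_chemtable(lib: ChemicalLibrary, new: ChemicalLibrary, precedence: str = "overwrite") -> ChemicalLibrary:
    """Merge ``new`` into ``lib`` field-by-field, returning a new library.

    New fields fill gaps; conflicting scalar fields are resolved per
    ``precedence`` ("overwrite" takes the new value, "keep_existing" keeps
    the old and logs a warning on MW conflicts).  Provenance is updated per
    replaced field.
    """
    if precedence not in ("overwrite", "keep_existing"):
        raise ValueError(f"unknown precedence {precedence!r}")
    merged = ChemicalLibrary(sources=tuple(dict.fromkeys(lib.sources + new.sources)))
    for rec in lib.records.values():
        merged.records[rec.dtxsid] = replace(
            rec,
            Clint=dict(rec.Clint),
            fup=dict(rec.fup),
            Rblood2plasma_measured=dict(rec.Rblood2plasma_measured),
            references=dict(rec.references),
        )
    for rec in new.records.values():
        if rec.dtxsid not in merged.records:
            merged.add(rec)
            continue
        old = merged.records[rec.dtxsid]
        for fld in ("MW", "logP", "logHenry", "caco2_papp", "name", "casrn"):
            new_v = getattr(rec, fld)
            old_v = getattr(old, fld)
            absent_old = old_v in (None, "") or (isinstance(old_v, float) and np.isnan(old_v))
            absent_new = new_v in (None, "") or (isinstance(new_v, float) and np.isnan(new_v))
            if absent_new:
                continue
            if absent_old:
                setattr(old, fld, new_v)
                old.references[fld] = f"filled from {new.sources or 'merge'}"
            elif new_v != old_v:
                if precedence == "overwrite":
                    setattr(old, fld, new_v)
                    old.references[fld] = f"replaced (was {old_v!r})"
                else:
                    if fld == "MW":
                        log.warning(
                            "add_chemtable: conflicting MW for %s (%r vs %r); keeping existing",
                            rec.dtxsid, old_v, new_v,
                        )
        if rec.pKa_donor and (precedence == "overwrite" or not old.pKa_donor):
            old.pKa_donor = rec.pKa_donor
        if rec.pKa_accept and (precedence == "overwrite" or not old.pKa_accept):
            old.pKa_accept = rec.pKa_accept
        if rec.chem_class:
            old.chem_class = old.chem_class | rec.chem_class
        for attr in ("Clint", "fup", "Rblood2plasma_measured"):
            tgt, src = getattr(old, attr), getattr(rec, attr)
            for sp, v in src.items():
                if sp not in tgt or precedence == "overwrite":
                    if sp in tgt and precedence == "overwrite":
                        old.references[f"{attr}.{sp}"] = "replaced"
                    tgt[sp] = v
    return merged


def get_cheminfo(
    lib: ChemicalLibrary,
    model: str = "3compartmentss",
    species: str = "Human",
    default_to_human: bool = True,
    info: list[str] | None = None,
) -> pd.DataFrame:
    """List the chemicals with sufficient data to run a given model.

    Applies the model's DataRequirements: all required fields present
    (after the human-default fallback), the fup==0 rule, the volatility
    (log Henry) cutoff, and chemical-class exclusions.  With
    ``exclude_fup_zero=False`` a fup recorded as 0 is retained and flagged
    for the downstream 0.5% default substitution.
    """
    from .models import get_model  # late import: avoids cycle

    reqs = get_model(model).data_requirements
    info = list(info) if info else ["dtxsid"]
    valid_info = {"dtxsid", "casrn", "name", "MW", "logP", "logHenry", "caco2_papp"}
    for f in info:
        if f not in valid_info:
            raise ValueError(f"unknown info field {f!r}; valid: {sorted(valid_info)}")
    rows = []
    for rec in lib.records.values():
        ok = all(rec.has_field(p, species, default_to_human) for p in reqs.required_params)
        if not ok:
            continue
        flagged_default_fup = False
        if "fup" in reqs.required_params:
            fup_uv, _ = get_field(rec, "fup", species, default_to_human)
            if fup_uv.point == 0.0:
                if reqs.exclude_fup_zero:
                    continue
                flagged_default_fup = True
        if reqs.log_henry_threshold is not None:
            if rec.logHenry is not None and rec.logHenry > reqs.log_henry_threshold:
                continue
        if rec.chem_class & reqs.chem_class_filter:
            continue
        row = {f: getattr(rec, f) for f in info}
        row["fup_default_flagged"] = flagged_default_fup
        rows.append(row)
    return pd.DataFrame(rows, columns=info + ["fup_default_flagged"])


def get_param(
    lib: ChemicalLibrary,
    id: str,
    field: str,
    species: str = "Human",
    default_to_human: bool = True,
):
    """Retrieve a single parameter value with its provenance."""
    rec = lib[id]
    return get_field(rec, field, species, default_to_human)


# ---------------------------------------------------------------------------
# synthetic library

def generate_synthetic_library(
    n: int, seed: int = 0, volatile_fraction: float = 0.2
) -> ChemicalLibrary:
    """Generate a reproducible synthetic chemical library.

    Distributions emulate the spread of a real high-throughput screening
    library: MW lognormal (median 250 g/mol, GSD 1.6); logP ~ N(2, 1.5);
    fup logit-normal with 10% of records stored as 3-tuples and 5% recorded
    as 0 (failed assay); Clint zero-inflated lognormal with 20% stored as
    4-tuples; ``volatile_fraction`` of records volatile
    (logHenry ~ U(-4, -1)), the rest U(-10, -6); 5% tagged "PFAS".
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0.0 <= volatile_fraction <= 1.0):
        raise ValueError("volatile_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lib = ChemicalLibrary(sources=(f"synthetic(seed={seed})",))
    for i in range(n):
        mw = float(np.exp(rng.normal(np.log(250.0), np.log(1.6))))
        logp = float(rng.normal(2.0, 1.5))
        # ionization: 30% monoprotic acids, 20% monoprotic bases, rest neutral
        u = rng.random()
        pka_d: tuple[float, ...] = ()
        pka_a: tuple[float, ...] = ()
        if u < 0.30:
            pka_d = (float(rng.uniform(3.0, 10.0)),)
        elif u < 0.50:
            pka_a = (float(rng.uniform(4.0, 10.0)),)
        volatile = rng.random() < volatile_fraction
        log_henry = float(rng.uniform(-4.0, -1.0)) if volatile else float(rng.uniform(-10.0, -6.0))

        # fup: logit-normal, median ~0.1; 5% failed assays recorded as 0
        if rng.random() < 0.05:
            fup_uv = UncertainValue(0.0)
        else:
            z = rng.normal(-2.2, 1.2)
            point = float(1.0 / (1.0 + np.exp(-z)))
            if rng.random() < 0.10:
                lo = float(1.0 / (1.0 + np.exp(-(z - 0.5))))
                hi = float(1.0 / (1.0 + np.exp(-(z + 0.5))))
                fup_uv = UncertainValue(point, lo, hi)
            else:
                fup_uv = UncertainValue(point)

        # Clint: zero-inflated lognormal (15% non-clearing), 20% as 4-tuples
        if rng.random() < 0.15:
            cl_uv = UncertainValue(0.0)
        else:
            m = float(np.exp(rng.normal(np.log(10.0), np.log(3.0))))
            if rng.random() < 0.20:
                gsd = 1.5
                cl_uv = UncertainValue(
                    m, m / gsd**1.96, m * gsd**1.96, float(rng.uniform(0.0, 0.1))
                )
            else:
                cl_uv = UncertainValue(m)

        rec = ChemicalRecord(
            dtxsid=f"DTXSID_SYN{i:05d}",
            casrn=f"{1000 + i}-00-{i % 10}",
            name=f"synthchem-{i:05d}",
            MW=mw,
            logP=logp,
            pKa_donor=pka_d,
            pKa_accept=pka_a,
            logHenry=log_henry,
            Clint={"Human": cl_uv},
            fup={"Human": fup_uv},
            chem_class=frozenset({"PFAS"}) if rng.random() < 0.05 else frozenset(),
        )
        # partial coverage mirroring real libraries
        if rng.random() < 0.30:
            rec.Rblood2plasma_measured["Human"] = float(np.exp(rng.normal(0.0, 0.4)))
        if rng.random() < 0.50:
            rec.caco2_papp = float(10.0 ** rng.normal(0.5, 0.7))
        if rng.random() < 0.30:
            rec.Clint["Rat"] = UncertainValue(float(np.exp(rng.normal(np.log(12.0), np.log(3.0)))))
            rec.fup["Rat"] = UncertainValue(float(1.0 / (1.0 + np.exp(-rng.normal(-2.2, 1.2)))))
        lib.add(rec)
    return lib
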