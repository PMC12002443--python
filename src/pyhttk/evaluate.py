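"""Model evaluation: log-scale error statistics, comparison against
concentration-vs-time observations, the package benchmark suite, and a
synthetic observation generator.

The headline statistic is the root mean squared error on the log10 scale
(RMSLE) between predicted and observed concentrations.  Because data
availability varies wildly between chemicals, the recommended convention
first averages squared log-errors within each chemical and then across
chemicals, so data-rich chemicals do not dominate.  R² is reported as
total explained variance (predicted vs observed), not a regression R²,
and can be negative when predictions do worse than the observed mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import ChemicalLibrary, get_cheminfo
from .models.dosing import DoseRegimen
from .models.solve import solve_model
from .monte_carlo import MCConfig, calc_mc_css
from .parameterize import parameterize_model
from .steady_state import calc_analytic_css
from .units import Quantity, UnitContext, convert_units

__all__ = [
    "CvTRecord",
    "BenchmarkReport",
    "rmsle",
    "r2_explained_variance",
    "compare_to_observations",
    "generate_synthetic_observations",
    "benchmark_suite",
]


@dataclass(frozen=True)
class CvTRecord:
    """One observed concentration at one time in one experimental condition."""

    chem_id: str
    species: str
    route: str
    dose: float
    dose_units: str
    time_h: float
    conc: float
    conc_units: str = "uM"
    medium: str = "plasma"
    study_id: str = ""
    exposure_h: float | None = None  # inhalation exposure duration

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise ValueError("conc must be >= 0")
        if self.time_h < 0:
            raise ValueError("time must be >= 0")


def rmsle(
    pred,
    obs,
    per_chemical_first: bool = False,
    chem_ids=None,
    floor: float | None = None,
) -> float:
    """Root mean squared error on the log10 scale.

    With ``per_chemical_first`` the mean squared log-error is computed
    within each chemical, then averaged across chemicals, before the root
    — the recommended convention when data per chemical is unbalanced.
    Nonpositive values are an error unless a ``floor`` (e.g. LOQ/2) is
    given.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have the same length")
    if floor is not None:
        pred = np.maximum(pred, floor)
        obs = np.maximum(obs, floor)
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise ValueError("nonpositive values; supply a floor to clip them")
    sq = (np.log10(pred) - np.log10(obs)) ** 2
    if per_chemical_first:
        if chem_ids is None:
            raise ValueError("per_chemical_first requires chem_ids")
        chem_ids = np.asarray(chem_ids)
        means = [sq[chem_ids == c].mean() for c in pd.unique(chem_ids)]
        return float(np.sqrt(np.mean(means)))
    return float(np.sqrt(sq.mean()))


def r2_explained_variance(pred, obs, log_scale: bool = False) -> float:
    """Total explained variance: 1 - SS_res/SS_tot of predicted vs observed."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    if log_scale:
        pred, obs = np.log10(pred), np.log10(obs)
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise ZeroDivisionError("observations have zero variance; R2 undefined")
    return float(1.0 - np.sum((obs - pred) ** 2) / ss_tot)


def _predict_condition(lib, model, records: list[CvTRecord], options, rtol, atol):
    """Simulate one experimental condition and predict at observation times."""
    r0 = records[0]
    chem = lib[r0.chem_id]
    times_d = sorted({r.time_h / 24.0 for r in records})
    t_end = max(times_d[-1] * 1.05, times_d[-1] + 1e-3)
    grid = np.unique(np.concatenate([[0.0], np.linspace(0.0, t_end, 200), times_d]))
    if r0.route == "inhalation":
        exposure_d = (r0.exposure_h if r0.exposure_h else r0.time_h) / 24.0
        regimen = DoseRegimen(
            route="inhalation",
            forcing_series=(
                (0.0, r0.dose, r0.dose_units),
                (exposure_d, 0.0, r0.dose_units),
            ),
        )
    else:
        regimen = DoseRegimen(
            route=r0.route, initial_dose=r0.dose, input_units=r0.dose_units
        )
    medium_var = {"plasma": "Cplasma", "blood": "Cven", "exhaled": "Cendexh"}
    needed = sorted({medium_var[r.medium] for r in records})
    res = solve_model(
        model, chem=lib[r0.chem_id], species=r0.species, times=grid,
        regimen=regimen, monitor_vars=needed, options=options,
        rtol=rtol, atol=atol,
    )
    preds = []
    for r in records:
        col = res.column(medium_var[r.medium])
        pred_uM = float(np.interp(r.time_h / 24.0, res.times, col))
        if r.conc_units != "uM":
            state = "gas" if r.medium == "exhaled" else "liquid"
            pred_uM = convert_units(
                Quantity(pred_uM, "uM"), r.conc_units, UnitContext(MW=chem.MW, state=state)
            ).value
        preds.append(pred_uM)
    return preds


def compare_to_observations(
    records: list[CvTRecord],
    lib: ChemicalLibrary,
    model: str = "pbtk",
    options: dict | None = None,
    floor: float = 1e-6,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> dict:
    """Simulate every experimental condition and score predictions.

    Groups records into conditions (chemical, species, route, dose,
    study), simulates each once, extracts matched-unit predictions at the
    observation times, and reports overall/per-species RMSLE and R² plus
    fold-error categories (fraction within 10-fold; fraction beyond
    100-fold).  Ineligible chemicals are skipped and counted.
    """
    if not records:
        return {"n": 0, "skipped": 0, "rmsle": None, "per_species": {}}
    eligible = set(get_cheminfo(lib, model=model)["dtxsid"])
    groups: dict[tuple, list[CvTRecord]] = {}
    skipped = 0
    for r in records:
        rec = lib.lookup(r.chem_id)
        if rec is None or rec.dtxsid not in eligible:
            skipped += 1
            continue
        key = (r.chem_id, r.species, r.route, r.dose, r.dose_units, r.study_id)
        groups.setdefault(key, []).append(r)
    rows = []
    for key, grp in groups.items():
        try:
            preds = _predict_condition(lib, model, grp, options, rtol, atol)
        except Exception as exc:
            warnings.warn(f"condition {key} failed: {exc!r}", stacklevel=2)
            skipped += len(grp)
            continue
        for r, p in zip(grp, preds):
            rows.append(
                {"chem_id": r.chem_id, "species": r.species, "pred": p, "obs": r.conc}
            )
    if not rows:
        return {"n": 0, "skipped": skipped, "rmsle": None, "per_species": {}}
    df = pd.DataFrame(rows)
    pred = np.maximum(df["pred"].to_numpy(), floor)
    obs = np.maximum(df["obs"].to_numpy(), floor)
    ratio = np.abs(np.log10(pred) - np.log10(obs))
    out = {
        "n": len(df),
        "skipped": skipped,
        "rmsle": rmsle(pred, obs),
        "rmsle_per_chemical": rmsle(
            pred, obs, per_chemical_first=True, chem_ids=df["chem_id"].to_numpy()
        ),
        "r2": r2_explained_variance(pred, obs, log_scale=True)
        if len(df) >= 2 and np.ptp(np.log10(obs)) > 0
        else None,
        "frac_within_10fold": float(np.mean(ratio <= 1.0)),
        "frac_beyond_100fold": float(np.mean(ratio > 2.0)),
        "per_species": {},
        "table": df,
    }
    for sp, sub in df.groupby("species"):
        p = np.maximum(sub["pred"].to_numpy(), floor)
        o = np.maximum(sub["obs"].to_numpy(), floor)
        slope, intercept = np.polyfit(np.log10(p), np.log10(o), 1) if len(sub) >= 2 else (np.nan, np.nan)
        out["per_species"][sp] = {
            "n": len(sub),
            "rmsle": rmsle(p, o),
            "log10_regression_slope": float(slope),
            "log10_regression_intercept": float(intercept),
        }
    return out


def generate_synthetic_observations(
    lib: ChemicalLibrary,
    model: str = "pbtk",
    n_conditions: int = 50,
    noise_sd_log10: float = 0.5,
    seed: int = 0,
    species: str = "Human",
    obs_per_condition: int = 4,
    options: dict | None = None,
) -> list[CvTRecord]:
    """Simulate randomized dosing conditions and add multiplicative log-noise.

    Emulates an in vivo concentration-vs-time evaluation set: for each
    condition a random eligible chemical, route and dose are drawn, the
    model is solved, observation times are sampled, and lognormal noise of
    the requested log10 sd is applied.  Reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    eligible = list(get_cheminfo(lib, model=model, species=species)["dtxsid"])
    if not eligible:
        raise ValueError(f"no chemicals in the library are eligible for {model!r}")
    records: list[CvTRecord] = []
    for c in range(n_conditions):
        chem_id = str(rng.choice(eligible))
        route = str(rng.choice(["oral", "iv"]))
        dose = float(rng.uniform(0.5, 10.0))
        times_h = np.sort(rng.uniform(0.5, 48.0, size=obs_per_condition))
        grid = np.unique(np.concatenate([[0.0], times_h / 24.0, [48.0 / 24.0 + 0.1]]))
        res = solve_model(
            model,
            chem=lib[chem_id],
            species=species,
            times=grid,
            regimen=DoseRegimen(route=route, initial_dose=dose, input_units="mg/kg"),
            monitor_vars=("Cplasma",),
            options=options,
            rtol=1e-6,
            atol=1e-9,
        )
        for t_h in times_h:
            clean = float(np.interp(t_h / 24.0, res.times, res.column("Cplasma")))
            noisy = clean * 10.0 ** rng.normal(0.0, noise_sd_log10)
            records.append(
                CvTRecord(
                    chem_id=chem_id,
                    species=species,
                    route=route,
                    dose=dose,
                    dose_units="mg/kg",
                    time_h=float(t_h),
                    conc=noisy,
                    conc_units="uM",
                    study_id=f"synthetic-{c:04d}",
                )
            )
    return records


@dataclass
class BenchmarkReport:
    """Named statistics from the package benchmark suite."""

    N_steady_state: int
    unit_ratio_analytic: float
    unit_ratio_mc: float
    unit_ratio_solve: float
    RMSLE_noMC: float
    N_noMC: int
    RMSLE_invivo_css: float | None = None
    RMSLE_wetmore: float | None = None
    failures: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "N_steady_state": self.N_steady_state,
            "unit_ratio_analytic": self.unit_ratio_analytic,
            "unit_ratio_mc": self.unit_ratio_mc,
            "unit_ratio_solve": self.unit_ratio_solve,
            "RMSLE_noMC": self.RMSLE_noMC,
            "N_noMC": self.N_noMC,
            "RMSLE_invivo_css": self.RMSLE_invivo_css,
            "RMSLE_wetmore": self.RMSLE_wetmore,
            "failures": list(self.failures),
        }


def benchmark_suite(
    lib: ChemicalLibrary,
    n_nomc: int = 20,
    mc_config: MCConfig | None = None,
    wetmore_reference: dict | None = None,
    invivo_css: dict | None = None,
    options: dict | None = None,
) -> BenchmarkReport:
    """Package-level performance checks and statistics.

    * N_steady_state: chemicals with sufficient data for steady-state IVIVE
      (eligibility for the default 3compartmentss model);
    * unit ratios: (Css in mg/L ÷ Css in µM) × 1000/MW for the analytic,
      Monte Carlo, and full-solve paths — must be 1;
    * RMSLE_noMC: log-error between Monte Carlo median Css and the
      non-varied analytic Css across the library;
    * optional RMSLE against user-supplied in vivo Css or reference
      steady-state values (keyed by chemical id, µM at 1 mg/kg/day).
    """
    failures: list[str] = []
    eligible = get_cheminfo(lib, model="3compartmentss")
    n_ss = len(eligible)

    ids = list(get_cheminfo(lib, model="pbtk")["dtxsid"])
    if not ids:
        raise ValueError("no pbtk-eligible chemicals in the library")
    probe = lib[ids[0]]
    mw = probe.MW

    css_uM = calc_analytic_css("pbtk", chem=probe, options=options, lib=lib)
    css_mgL = calc_analytic_css(
        "pbtk", chem=probe, output_units="mg/L", options=options, lib=lib
    )
    unit_ratio_analytic = (css_mgL / css_uM) * 1000.0 / mw

    cfg = mc_config or MCConfig(n=10, invitrouv=False)
    mc_uM = calc_mc_css("pbtk", probe, config=cfg, options=options, lib=lib)
    params = parameterize_model("pbtk", probe, options=options, lib=lib)
    mc_css_med = mc_uM["median"]
    mc_mgL = convert_units(
        Quantity(mc_css_med, "uM"), "mg/L", UnitContext(MW=mw)
    ).value
    unit_ratio_mc = (mc_mgL / mc_css_med) * 1000.0 / mw

    times = np.linspace(0.0, 1.0, 25)
    regimen = DoseRegimen(route="oral", initial_dose=1.0, input_units="mg/kg")
    res = solve_model(
        "pbtk", params=params, times=times, regimen=regimen,
        monitor_vars=("Cplasma",), output_units=None, rtol=1e-6, atol=1e-9,
    )
    res_mgL = solve_model(
        "pbtk", params=params, times=times, regimen=regimen,
        monitor_vars=("Cplasma",), output_units={"Cplasma": "mg/L"},
        rtol=1e-6, atol=1e-9,
    )
    c_uM = res.column("Cplasma")[-1]
    c_mgL = res_mgL.column("Cplasma")[-1]
    unit_ratio_solve = (c_mgL / c_uM) * 1000.0 / mw

    for name, val in (
        ("analytic", unit_ratio_analytic),
        ("mc", unit_ratio_mc),
        ("solve", unit_ratio_solve),
    ):
        if abs(val - 1.0) > 1e-9:
            failures.append(f"unit ratio {name} = {val!r} differs from 1")

    # noMC: Monte Carlo median Css vs non-varied analytic Css
    nomc_pred, nomc_ref, n_used = [], [], 0
    cfg_nomc = mc_config or MCConfig(n=200, invitrouv=True, seed=17)
    for cid in ids[:n_nomc]:
        chem = lib[cid]
        try:
            analytic = calc_analytic_css("pbtk", chem=chem, options=options, lib=lib)
            mc = calc_mc_css("pbtk", chem, config=cfg_nomc, options=options, lib=lib)
        except (ZeroDivisionError, ValueError):
            continue
        if analytic > 0 and np.isfinite(mc["median"]) and mc["median"] > 0:
            nomc_pred.append(mc["median"])
            nomc_ref.append(analytic)
            n_used += 1
    rmsle_nomc = rmsle(nomc_pred, nomc_ref) if n_used else float("nan")

    rmsle_invivo = None
    if invivo_css:
        pairs = [
            (calc_analytic_css("pbtk", chem=lib[cid], options=options, lib=lib), v)
            for cid, v in invivo_css.items()
            if lib.lookup(cid) is not None
        ]
        if pairs:
            rmsle_invivo = rmsle([p for p, _ in pairs], [o for _, o in pairs])

    rmsle_wetmore = None
    if wetmore_reference:
        cfgw = mc_config or MCConfig(n=200, invitrouv=True, seed=23, quantiles=(0.95,))
        pairs = []
        for cid, ref in wetmore_reference.items():
            if lib.lookup(cid) is None:
                continue
            mc = calc_mc_css("pbtk", lib[cid], config=cfgw, options=options, lib=lib)
            q95 = mc["quantiles"][0.95]
            if np.isfinite(q95) and q95 > 0 and ref > 0:
                pairs.append((q95, ref))
        if pairs:
            rmsle_wetmore = rmsle([p for p, _ in pairs], [o for _, o in pairs])

    return BenchmarkReport(
        N_steady_state=n_ss,
        unit_ratio_analytic=float(unit_ratio_analytic),
        unit_ratio_mc=float(unit_ratio_mc),
        unit_ratio_solve=float(unit_ratio_solve),
        RMSLE_noMC=float(rmsle_nomc),
        N_noMC=n_used,
        RMSLE_invivo_css=rmsle_invivo,
        RMSLE_wetmore=rmsle_wetmore,
        failures=failures,
    )
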