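"""Four-step Monte Carlo propagation of uncertainty and variability.

Starting from the deterministic baseline parameter set, each simulated
individual is built in four ordered steps:

1. user-listed parameters drawn from truncated (and optionally censored)
   normal distributions;
2. population physiology (human only) from a parametric correlated-
   lognormal sampler — a distributional stand-in with the same interface
   as a survey-backed population simulator;
3. chemical-specific in vitro parameters (Clint, fup, Caco-2) sampled
   from their Bayesian uncertainty tuples where available;
4. recalculation of derived quantities (tissue partition coefficients,
   first-pass bioavailability, clearances) per individual.

On top of the sample table sit the steady-state endpoints: ``calc_mc_css``
(quantiles of Css for a unit dose rate), ``calc_mc_oral_equiv`` (reverse
dosimetry: the daily dose producing a target plasma concentration), and
``calc_mc_tk`` (full ODE solves, per-time mean and sd).  With every
variance source disabled each endpoint reduces exactly to its
deterministic counterpart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .chem import ChemicalRecord, UncertainValue, get_field
from .models.registry import get_model
from .models.solve import solve_model
from .parameterize import (
    ALLOMETRIC_EXPONENT,
    ParameterSet,
    calc_oral_bioavailability,
    load_physiology,
    load_tissue_table,
    parameterize_model,
)
from .partition import load_partition_config, lump_tissues, predict_partitioning_schmitt
from .steady_state import calc_analytic_css

__all__ = [
    "MCConfig",
    "PopulationSpec",
    "ParameterSampleTable",
    "sample_censored_truncated",
    "sample_population_physiology",
    "sample_invitro_uv",
    "create_mc_samples",
    "calc_mc_css",
    "calc_mc_oral_equiv",
    "calc_mc_tk",
]

Z95 = 1.959963984540054


@dataclass(frozen=True)
class PopulationSpec:
    """Parametric population variability (lognormal CVs + rank correlation)."""

    cv_bw: float = 0.20
    cv_flow: float = 0.30
    cv_gfr: float = 0.30
    cv_hepatocellularity: float = 0.30
    rank_correlation: float = 0.4  # shared size factor across BW/flows/GFR


@dataclass
class MCConfig:
    n: int = 1000
    seed: int = 1234
    vary_params: dict = field(default_factory=dict)  # param -> CV
    censored_params: dict = field(default_factory=dict)  # param -> LOD
    httkpop: bool = False
    population: PopulationSpec = field(default_factory=PopulationSpec)
    invitrouv: bool = True
    default_invitro_cv: float = 0.3
    clint_pvalue_threshold: float = 0.05
    clint_zero_mode: str = "bernoulli"  # or "hard" (p-value cutoff)
    quantiles: tuple[float, ...] = (0.95,)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for p, cv in self.vary_params.items():
            if cv <= 0:
                raise ValueError(f"CV for {p!r} must be > 0")
        for q in self.quantiles:
            if not (0.0 < q < 1.0):
                raise ValueError("quantiles must lie in (0, 1)")


@dataclass
class ParameterSampleTable:
    """n-draw matrix of model parameters with per-column provenance tags."""

    table: pd.DataFrame
    provenance: dict  # column -> {"baseline","step1","pop","invitro","recalc"}
    model: str
    species: str
    seed: int

    def __len__(self) -> int:
        return len(self.table)


def sample_censored_truncated(
    baseline: float,
    cv: float,
    lod: float | None = None,
    n: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Truncated-normal draws around a baseline, optionally LOD-censored.

    Normal(mean=baseline, sd=cv*baseline) truncated at zero; draws below
    the limit of detection are replaced uniformly on [0, LOD).
    """
    if baseline < 0:
        raise ValueError("baseline must be >= 0")
    if cv <= 0:
        raise ValueError("cv must be > 0")
    rng = rng or np.random.default_rng()
    sd = cv * baseline
    if sd == 0:
        draws = np.full(n, baseline)
    else:
        a = (0.0 - baseline) / sd  # truncate at zero
        draws = stats.truncnorm.rvs(a, np.inf, loc=baseline, scale=sd, size=n, random_state=rng)
    if lod is not None:
        below = draws < lod
        draws[below] = rng.uniform(0.0, lod, size=int(below.sum()))
    return draws


def sample_population_physiology(
    species: str,
    spec: PopulationSpec,
    n: int,
    rng: np.random.Generator,
    physiology=None,
) -> pd.DataFrame:
    """Correlated lognormal draws of population physiology (human only).

    Returns per-individual BW (kg) and multiplicative factors for flows,
    GFR, and hepatocellularity, correlated through a shared body-size
    factor (Gaussian copula).  Raises for non-human species: the
    population distributions describe a human population.
    """
    if species.lower() != "human":
        raise ValueError(
            "population physiology sampling describes a human population and "
            "should not be used for non-human species"
        )
    phys = physiology or load_physiology("Human")
    cvs = np.array([spec.cv_bw, spec.cv_flow, spec.cv_gfr, spec.cv_hepatocellularity])
    sigmas = np.sqrt(np.log1p(cvs**2))
    r = spec.rank_correlation
    corr = np.full((4, 4), r)
    np.fill_diagonal(corr, 1.0)
    L = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, 4)) @ L.T
    # lognormal with median = reference value (factors have median 1)
    bw = phys.BW * np.exp(sigmas[0] * z[:, 0])
    return pd.DataFrame(
        {
            "BW": bw,
            "flow_factor": np.exp(sigmas[1] * z[:, 1]),
            "gfr_factor": np.exp(sigmas[2] * z[:, 2]),
            "hepatocellularity_factor": np.exp(sigmas[3] * z[:, 3]),
        }
    )


def _split_normal(mu, sigma_lo, sigma_hi, n, rng):
    """Two-piece normal: matches the median and both 95% bounds exactly."""
    z = rng.standard_normal(n)
    return mu + np.where(z < 0, sigma_lo, sigma_hi) * z


def _lognormal_from_tuple(uv: UncertainValue, n, rng, default_cv):
    """Quantile-matched (split-)lognormal draws for a positive parameter."""
    if uv.point <= 0:
        return np.zeros(n)
    mu = np.log(uv.point)
    if uv.has_bounds and uv.l95 > 0:
        s_lo = (mu - np.log(uv.l95)) / Z95
        s_hi = (np.log(uv.u95) - mu) / Z95
    else:
        s_lo = s_hi = np.sqrt(np.log1p(default_cv**2))
    return np.exp(_split_normal(mu, s_lo, s_hi, n, rng))


def _logitnormal_from_tuple(uv: UncertainValue, n, rng, default_cv):
    """Quantile-matched (split-)logit-normal draws for a fraction in (0, 1]."""
    point = min(max(uv.point, 1e-6), 1.0 - 1e-9)
    mu = logit(point)
    if uv.has_bounds and 0 < uv.l95 < uv.u95 < 1:
        s_lo = (mu - logit(uv.l95)) / Z95
        s_hi = (logit(uv.u95) - mu) / Z95
    else:
        # for small fractions d(logit p) ~ dp/p, so a logit-sd of the CV
        # gives roughly that relative spread
        s_lo = s_hi = default_cv
    draws = expit(_split_normal(mu, s_lo, s_hi, n, rng))
    return np.clip(draws, 1e-9, 1.0)


def sample_invitro_uv(
    chem: ChemicalRecord,
    config: MCConfig,
    n: int,
    rng: np.random.Generator,
    species: str = "Human",
    default_to_human: bool = True,
) -> dict:
    """Step-three draws of chemical-specific in vitro parameters.

    Clint: with probability ``p_no_effect`` an individual draw is zero
    (no observed clearance), otherwise lognormal matched to the Bayesian
    (median, l95, u95); in "hard" mode the zero branch is all-or-nothing
    at the p-value threshold.  fup: logit-normal on (0, 1].  Caco-2:
    lognormal at the default CV.
    """
    out: dict[str, np.ndarray] = {}
    clint_uv, _ = get_field(chem, "Clint", species, default_to_human)
    draws = _lognormal_from_tuple(clint_uv, n, rng, config.default_invitro_cv)
    p0 = clint_uv.p_no_effect
    if p0 is not None and p0 > 0:
        if config.clint_zero_mode == "hard":
            if p0 > config.clint_pvalue_threshold:
                draws = np.zeros(n)
        else:
            draws = np.where(rng.random(n) < p0, 0.0, draws)
    out["Clint"] = draws

    fup_uv, _ = get_field(chem, "fup", species, default_to_human)
    if fup_uv.point == 0.0:
        from .chem import DEFAULT_FUP

        fup_uv = UncertainValue(DEFAULT_FUP)
    out["fup"] = _logitnormal_from_tuple(fup_uv, n, rng, config.default_invitro_cv)

    if chem.caco2_papp is not None:
        out["caco2_papp"] = _lognormal_from_tuple(
            UncertainValue(chem.caco2_papp), n, rng, config.default_invitro_cv
        )
    return out


def create_mc_samples(
    model: str,
    chem: ChemicalRecord,
    species: str = "Human",
    config: MCConfig | None = None,
    options: dict | None = None,
    lib=None,
    baseline: ParameterSet | None = None,
) -> ParameterSampleTable:
    """Build the n-row Monte Carlo parameter table via the four-step process."""
    config = config or MCConfig()
    info = get_model(model)
    mc_info = info.mc
    rng = np.random.default_rng(config.seed)
    options = dict(options or {})
    if baseline is None:
        baseline = parameterize_model(model, chem, species, options, lib=lib)
    n = config.n
    table = pd.DataFrame({k: np.full(n, v) for k, v in baseline.values.items()})
    provenance = {k: "baseline" for k in table.columns}

    # warn when a step-1 parameter will be overwritten later
    later = set()
    if config.httkpop and mc_info:
        later |= set(mc_info.httkpop_params)
    if config.invitrouv and mc_info:
        later |= set(mc_info.invitro_params)
    overlap = (set(config.vary_params) | set(config.censored_params)) & later
    if overlap:
        warnings.warn(
            f"parameters {sorted(overlap)} are sampled in step 1 but will be "
            "overwritten by a later Monte Carlo step",
            stacklevel=2,
        )

    # Step 1: truncated/censored normals for user-listed parameters
    for pname, cv in config.vary_params.items():
        lod = config.censored_params.get(pname)
        table[pname] = sample_censored_truncated(baseline[pname], cv, lod, n, rng)
        provenance[pname] = "step1"
    for pname, lod in config.censored_params.items():
        if pname not in config.vary_params:
            table[pname] = sample_censored_truncated(
                baseline[pname], config.default_invitro_cv, lod, n, rng
            )
            provenance[pname] = "step1"

    phys = load_physiology(species, options.get("physiology_path"))
    tissues = options.get("tissue_table") or load_tissue_table()
    pconfig = options.get("partition_config") or load_partition_config()

    # Step 2: population physiology (human only)
    if config.httkpop:
        pop = sample_population_physiology(species, config.population, n, rng, phys)
        scale = (pop["BW"] / phys.BW) ** ALLOMETRIC_EXPONENT
        httkpop_params = set(mc_info.httkpop_params) if mc_info else set()

        def overwrite(name, values):
            if name in table.columns and (not httkpop_params or name in httkpop_params):
                table[name] = values
                provenance[name] = "pop"

        overwrite("BW", pop["BW"].to_numpy())
        for qname in ("Qcardiac", "Qalv", "Qgut", "Qliver", "Qkidney", "Qrest", "Qlung"):
            if qname in table.columns:
                overwrite(
                    qname,
                    baseline[qname]
                    * scale.to_numpy()
                    * pop["flow_factor"].to_numpy(),
                )
        overwrite("GFR", baseline["GFR"] * scale.to_numpy() * pop["gfr_factor"].to_numpy())
        for vname in ("Vgut", "Vliver", "Vkidney", "Vlung", "Vrest", "Vart", "Vven"):
            if vname in table.columns:
                overwrite(vname, baseline[vname] * (pop["BW"] / phys.BW).to_numpy())
        if "Clint_w" in table.columns:
            overwrite(
                "Clint_w",
                baseline["Clint_w"]
                * (pop["BW"] / phys.BW).to_numpy()
                * pop["hepatocellularity_factor"].to_numpy(),
            )

    # Step 3: in vitro chemical-specific uncertainty
    invitro: dict = {}
    if config.invitrouv:
        invitro = sample_invitro_uv(
            chem, config, n, rng, species, options.get("default_to_human", True)
        )
        if "fup" in table.columns:
            table["fup"] = invitro["fup"]
            provenance["fup"] = "invitro"
        if "Clint" in table.columns:
            table["Clint"] = invitro["Clint"]
            provenance["Clint"] = "invitro"
            if "Clint_w" in table.columns:
                # rescale whole-liver Clint by the drawn assay ratio
                base_clint = baseline["Clint"] if baseline["Clint"] > 0 else 1.0
                table["Clint_w"] = table["Clint_w"] * invitro["Clint"] / base_clint
                provenance["Clint_w"] = "invitro"

    # Step 4: recalculate dependent parameters per individual
    if mc_info and (mc_info.calcpc or mc_info.firstpass) and (
        config.invitrouv or config.httkpop or config.vary_params
    ):
        kp_cols = [c for c in table.columns if c.startswith("K") and c.endswith("2pu")]
        if mc_info.calcpc and kp_cols:
            for i in range(n):
                fup_i = float(table.at[i, "fup"])
                if not (0.0 < fup_i <= 1.0):
                    continue
                kp = predict_partitioning_schmitt(
                    chem, fup_i, tissues,
                    calibrated=options.get("regression_calibrated", False),
                    config=pconfig,
                )
                lumped_kp, _, _ = lump_tissues(kp, tissues, info.lumping_scheme)
                for comp, val in lumped_kp.items():
                    col = f"K{comp}2pu"
                    if col in table.columns:
                        table.at[i, col] = val
                if "Krbc2pu" in table.columns:
                    table.at[i, "Krbc2pu"] = kp["red blood cells"]
            for col in kp_cols:
                provenance[col] = "recalc"
        if mc_info.firstpass and {"Fgut", "Fhep"} <= set(table.columns):
            q_liver_total = (
                table["Qgut"] + table["Qliver"]
                if {"Qgut", "Qliver"} <= set(table.columns)
                else np.full(n, np.nan)
            )
            for i in range(n):
                fabs, fgut, fhep, _ = calc_oral_bioavailability(
                    chem,
                    float(table.at[i, "fup"]),
                    float(table.at[i, "Clint_w"]),
                    float(q_liver_total.iloc[i])
                    if not np.isscalar(q_liver_total)
                    else float(q_liver_total),
                    float(table.at[i, "Rblood2plasma"]),
                )
                table.at[i, "Fgut"] = fgut
                table.at[i, "Fhep"] = fhep
            provenance["Fgut"] = provenance["Fhep"] = "recalc"
        if "CLh" in table.columns and {"Qgut", "Qliver", "Clint_w", "fup"} <= set(table.columns):
            ql = table["Qgut"] + table["Qliver"]
            num = ql * table["fup"] * table["Clint_w"]
            den = ql + table["fup"] * table["Clint_w"]
            table["CLh"] = np.where(num > 0, num / den, 0.0)
            provenance["CLh"] = "recalc"
        if "kelim" in table.columns and "Vdist" in table.columns:
            cl_tot = table["CLh"] + table["fup"] * table["GFR"]
            table["kelim"] = cl_tot / table["Vdist"]
            provenance["kelim"] = "recalc"
        if mc_info.propagateuv_func is not None:
            table = mc_info.propagateuv_func(table)
            # caller-defined: provenance left as-is

    return ParameterSampleTable(
        table=table, provenance=provenance, model=model, species=species, seed=config.seed
    )


def _row_params(baseline: ParameterSet, row: pd.Series) -> ParameterSet:
    p = baseline.copy()
    p.values.update({k: float(v) for k, v in row.items()})
    return p


def calc_mc_css(
    model: str,
    chem: ChemicalRecord,
    species: str = "Human",
    config: MCConfig | None = None,
    dose_rate: float = 1.0,
    dose_units: str = "mg/kg/day",
    options: dict | None = None,
    lib=None,
    samples: ParameterSampleTable | None = None,
) -> dict:
    """Monte Carlo quantiles of the steady-state plasma concentration.

    Evaluates the analytic Css per sampled individual for the given dose
    rate (the IVIVE convention is 1 mg/kg/day) and returns the requested
    quantiles plus the median and draws.
    """
    config = config or MCConfig()
    info = get_model(model)
    if info.steady_state is None:
        raise ValueError(f"model {model!r} has no analytic steady state for MC Css")
    baseline = parameterize_model(model, chem, species, options, lib=lib)
    if samples is None:
        samples = create_mc_samples(
            model, chem, species, config, options, lib=lib, baseline=baseline
        )
    css = np.empty(len(samples))
    for i, (_, row) in enumerate(samples.table.iterrows()):
        p = _row_params(baseline, row)
        try:
            css[i] = calc_analytic_css(
                model, params=p, dose_rate=dose_rate, dose_units=dose_units
            )
        except ZeroDivisionError:
            css[i] = np.inf
    finite = css[np.isfinite(css)]
    qs = {q: float(np.quantile(css, q)) for q in config.quantiles}
    return {
        "quantiles": qs,
        "median": float(np.median(css)),
        "mean": float(finite.mean()) if finite.size else float("inf"),
        "draws": css,
        "n_nonclearing": int(np.sum(~np.isfinite(css))),
    }


def calc_mc_oral_equiv(
    target_conc: float,
    model: str,
    chem: ChemicalRecord,
    species: str = "Human",
    config: MCConfig | None = None,
    options: dict | None = None,
    lib=None,
) -> dict:
    """Reverse-dosimetry IVIVE: daily dose producing a target plasma Css.

    Linearity makes the inversion exact: dose = target / Css(1 mg/kg/day).
    The dose at the qth Css quantile is the health-protective end (higher
    Css individuals need less external dose).
    """
    if not target_conc > 0:
        raise ValueError("target_conc must be > 0")
    config = config or MCConfig()
    mc = calc_mc_css(
        model, chem, species, config, dose_rate=1.0, dose_units="mg/kg/day",
        options=options, lib=lib,
    )
    draws = mc["draws"]
    zero = draws == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-Css draws excluded from oral-equivalent dose",
            stacklevel=2,
        )
    doses = {}
    for q, css_q in mc["quantiles"].items():
        doses[q] = float(target_conc / css_q) if css_q > 0 else float("inf")
    return {
        "quantile_doses": doses,
        "median_dose": float(target_conc / mc["median"]) if mc["median"] > 0 else float("inf"),
        "units": "mg/kg/day",
        "n_zero_css": int(zero.sum()),
    }


def calc_mc_tk(
    model: str,
    chem: ChemicalRecord,
    species: str = "Human",
    config: MCConfig | None = None,
    times=None,
    regimen=None,
    monitor_vars=None,
    options: dict | None = None,
    lib=None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> dict:
    """Full-model Monte Carlo: per-time mean and sd of each monitored variable."""
    config = config or MCConfig()
    info = get_model(model)
    if not info.solve_capable:
        raise ValueError(f"model {model!r} is not solve-capable")
    baseline = parameterize_model(model, chem, species, options, lib=lib)
    samples = create_mc_samples(
        model, chem, species, config, options, lib=lib, baseline=baseline
    )
    monitor_vars = list(monitor_vars or info.default_monitor_vars)
    results = []
    failures = 0
    times_out = None
    for _, row in samples.table.iterrows():
        p = _row_params(baseline, row)
        try:
            res = solve_model(
                model, params=p, times=times, regimen=regimen,
                monitor_vars=monitor_vars, rtol=rtol, atol=atol,
            )
            results.append(res.data[monitor_vars].to_numpy())
            if times_out is None:
                times_out = res.times
        except (RuntimeError, ValueError):
            failures += 1
    if not results:
        raise RuntimeError("all Monte Carlo solves failed")
    stack = np.stack(results)
    mean = stack.mean(axis=0)
    degenerate = bool((samples.table.nunique() <= 1).all())
    if stack.shape[0] > 1 and not degenerate:
        sd = stack.std(axis=0, ddof=1)
    else:
        # identical parameter rows: identical solves, sd exactly zero
        sd = np.zeros_like(mean)
    out = {"times": np.asarray(times_out), "n": stack.shape[0], "n_failed": failures}
    for j, var in enumerate(monitor_vars):
        out[var] = {"mean": mean[:, j], "sd": sd[:, j]}
    if stack.shape[0] == 1:
        out["sd_undefined"] = True
    return out
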