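# Methods

This note documents the models and numerical procedures implemented in
`pyhttk`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic study conditions do and do not establish.

## Scope and philosophy

`pyhttk` implements generic (chemical-independent) toxicokinetic models
parameterized by standardized chemical-specific quantities that can be
measured in vitro — intrinsic hepatic clearance (Clint, µL/min/10⁶
hepatocytes), fraction unbound in plasma (fup), blood:plasma ratio,
Caco-2 membrane permeability — plus physico-chemical properties (MW,
logP, pKa, Henry's law constant). The same model structure is reused
across thousands of chemicals; what varies is the parameterization. A
model registry (`ModelInfo`) declares each model's state variables,
parameters, derivative outputs with units and state of matter, dosing
routes, data-eligibility criteria, and steady-state / Monte Carlo
capabilities, so that core functions (eligibility queries, the solver,
steady-state and Monte Carlo wrappers, the benchmark suite) interact with
every model through the same contract.

## Chemical data semantics

* In vitro values may carry Bayesian uncertainty as comma-separated tuple
  strings: Clint as `median,l95,u95,p_no_effect` (the last element is the
  posterior probability that no clearance was observed) and fup as
  `median,l95,u95`. Single values are points without uncertainty.
* fup recorded as exactly 0 means the binding assay was attempted and
  failed because the chemical is highly bound. The raw 0 is preserved in
  the library; at parameterization a default of 0.5% unbound is
  substituted (option-controlled).
* Species-specific values are preferred; with `default_to_human` a human
  measurement backstops a missing species value, and the provenance
  records which was used.
* Model eligibility (`get_cheminfo`) additionally applies a volatility
  cutoff (chemicals with log10 Henry's law constant above a threshold,
  default −4.5 log10(atm·m³/mol), are excluded from liquid-only models —
  the threshold is configurable because no canonical value exists) and
  chemical-class exclusions (e.g. PFAS outside a model's domain).

## Tissue partitioning

Tissue:unbound-plasma partition coefficients use a component-based
equilibrium model in the Schmitt tradition. Each tissue is water +
neutral lipid + phospholipid membrane + protein (fractions in
`data/tissue_composition.csv`, a 11-tissue set plus red blood cells):

    Kp = f_water + f_nl·K_nl + f_pl·K_pl + f_protein·K_prot

* K_nl: octanol:water distribution of the species mix at the tissue pH.
  Ionization fractions come from Henderson–Hasselbalch with acid and base
  sites treated as independent equilibria; ionized species have their
  logP reduced by 3.7 log units (a standard logD assumption).
* K_pl: a membrane-affinity regression 10^(0.304·logP + 0.294) with
  multiplicative factors per charge state (cation 0.5, anion 0.05,
  zwitterion 0.5) reflecting electrostatic interaction with phospholipid
  headgroups.
* K_prot: inferred from plasma binding — a chemical that is (1−fup)/fup
  bound:free against ~7.5% plasma protein has affinity
  ((1−fup)/fup)/0.075, scaled by each tissue's protein fraction.

All constants live in `data/schmitt_calibration.yaml`. An optional
per-tissue affine calibration in log10 space can be layered on; the
shipped default is the identity (uncalibrated), because the published
calibrated coefficients belong to a specific training exercise and users
should supply their own regression if they want one.

Red blood cells are a row of the same composition table, so the
RBC:unbound-plasma coefficient falls out of the same predictor and feeds
the computed blood:plasma ratio `Rb2p = (1−hct) + hct·Krbc2pu·fup`. The
full blood:plasma cascade is: measured species value → measured human
value → computed from the RBC partition coefficient → library average of
measured values; the provenance label always states the branch taken.

The in vitro/in vivo fup correction accounts for plasma lipid missing
from the binding assay: `fup_corr = fup/(1 + Dow·f_lipid·fup)` with
f_lipid = 0.02. It is the identity for hydrophilic chemicals and strictly
lowers fup with lipophilicity; it can be disabled.

## Parameterization

* Clint is first corrected for binding in the hepatocyte incubation:
  fu_hep = 1/(1 + 0.005·density·10^(0.4·logP)), a monotone logistic
  association model (≈1 for hydrophilic chemicals, decreasing in logP).
  The functional form is a package choice — published alternatives have a
  quadratic logP term that is non-monotone at the hydrophilic end — and
  both constants are configurable.
* Whole-liver scaling: Clint/fu_hep × hepatocellularity (10⁶ cells/g
  liver) × liver mass, converted to L/h. The well-stirred model gives
  CLh = Q_liver·fup·Clint_w/(Q_liver + fup·Clint_w) < Q_liver.
* Oral bioavailability: Fabs from a logistic curve in log10 of the Caco-2
  permeability (midpoint 1e-6 cm/s, slope 1 per decade, both
  configurable; default 1 when no measurement exists); Fgut from a gut
  intrinsic clearance equal to **1% of the scaled hepatic Clint**
  competing with uptake into portal blood; Fhep =
  Q_liver/(Q_liver + fup·Clint_w/Rb2p) for first-pass hepatic survival.
* Flows, alveolar ventilation and GFR scale allometrically as BW^0.75
  (the standard ¾-power; configurable constant). Volumes scale linearly
  with BW. Physiology constants for Human and Rat ship in
  `data/physiology.csv`.
* Parameterization is a pure function of (chemical, species, options,
  constants files); the resulting `ParameterSet` must cover the
  registered model's parameter names exactly and passes a unit audit
  against the controlled vocabulary.

## Models

State is stored as amounts (µmol); concentrations are derived outputs.
This makes the mass balance exact by construction: at all times the sum
of compartment amounts plus the cumulative elimination accumulators
(urine, metabolism, unabsorbed dose, exhaled air) equals everything
administered plus everything inhaled, up to solver tolerance. Time is in
days internally; the AUC accumulator integrates the plasma concentration
(µM·day) inside the ODE, so day averages are exact integrals rather than
quadrature over output samples.

* **pbtk** — perfusion-limited compartments: gut lumen, gut, liver,
  kidney, lung, rest-of-body, arterial and venous blood. Blood leaves a
  tissue in equilibrium with it at `C_t·Rb2p/(Kp·fup)`. The liver
  receives the hepatic artery and the portal (gut) outflow; metabolism
  clears the unbound liver concentration at Clint_w, which reproduces
  well-stirred extraction at steady state. The kidney filters its
  unbound tissue concentration at GFR into a cumulative urine
  accumulator. Venous blood passes through the lung tissue before
  becoming arterial. Oral absorption drains the gut lumen first-order
  (ka, default 2.18/h); the fraction Fabs·Fgut enters gut tissue and the
  remainder accumulates as unabsorbed.
* **gas_pbtk** — the same body with alveolar gas exchange: blood
  returning to the lung equilibrates with alveolar air,
  `C_exch = (Qalv·C_inh_alv + QC·C_ven)/(QC + Qalv/Kblood2air)`; exhaled
  air is in equilibrium with post-exchange blood and is reported in both
  µM and ppmv. Kblood2air = (Rb2p/fup)/(HLC/(R·T_body)) comes from the
  Henry's law constant at body temperature; Rb2p/fup approximates the
  blood:water ratio through the unbound-plasma≈water link. A
  mucus/upper-respiratory compartment deposits a fraction (default 1%)
  of inhaled chemical and desorbs it first-order (default 1/h) into the
  gut lumen (swallowed); both constants are configurable stand-ins for
  airway-specific data. With zero exposure, no deposition and a very
  large Kblood2air the model collapses to pbtk (verified to 2%).
* **1compartment** — Vdist (plasma-referenced, from the same partition
  coefficients: Vblood + Σ V_t·Kp_t·fup) with
  kelim = (CLh + fup·GFR)/Vdist, plus first-order oral absorption. Its
  iv-bolus closed form is the solver oracle.
* **3compartmentss** — steady-state only (no ODE):
  Css = molar dose rate / (fup·GFR + CLh), registered solve-incapable.

Dosing is event-driven: doses add instantaneously to the route's target
state (oral → gut lumen, iv → venous blood); inhalation exposure is a
piecewise-constant forcing of air concentration. Event times are
integrated exactly by splitting the integration (scipy LSODA, default
rtol 1e-8/atol 1e-12); requested output times never need to include dose
times. `validate_model` probes each derivative routine with sentinel
states and rejects any permutation between the declared output ordering
and what the routine actually produces — the historically dangerous
failure mode, since a permuted declaration silently relabels columns
(e.g. a ppmv column reported as µM).

## Steady state

`calc_analytic_css` exploits linearity: for ODE models the right-hand
side is probed column-by-column at unit basis states (exact for a linear
system) to build A, and A·x = −b is solved for a continuous oral
infusion b; the plasma concentration at the solved state is Css. This
avoids hand-derived per-model formulas and their transcription risk. A
singular or negative solution flags a non-clearing chemical (no finite
steady state). `3compartmentss` uses its closed form directly. No
analytic steady state is provided for the gas model.

`calc_css` simulates repeated dosing (default 3 doses/day, a criterion
chosen to mirror typical exposure modeling) and declares quasi-steady
state on the first day whose day-averaged plasma concentration (from AUC
differences) changes less than the tolerance (default 1%) from the
previous day, returning that day. Chemicals still accumulating at the
horizon (default 180 d) are returned flagged non-converged with partial
output. Day-average detection was chosen over trough sampling because it
is robust to dosing phase. Note the day-to-day criterion is a stopping
rule, not an error bound: for slowly clearing chemicals (elimination
slower than ~0.2/day) a 1% day-to-day change can coexist with a several
percent gap to the true steady state; comparisons against the analytic
value in the tests therefore run at tolerance 0.001, under which
convergence within 100 days implies agreement within ~3%.

## Monte Carlo

`create_mc_samples` builds an n-row parameter table in four ordered
steps: (1) user-listed parameters from truncated normals
(mean = baseline, sd = CV·baseline, truncated at 0), optionally censored
— draws below the limit of detection are replaced uniformly on [0, LOD),
a documented substitute for an unspecified convention; (2) population
physiology (human only; requesting it for another species is an error)
from a parametric correlated-lognormal sampler — BW CV 20%, flows 30%,
GFR 30%, hepatocellularity 30%, rank correlation 0.4 through a shared
body-size factor. This is a distributional stand-in with the same
interface as a survey-backed population simulator, so one can drop in
later; it keeps the package free of external data. (3) in vitro
uncertainty: Clint draws are zero with probability p_no_effect
(per-draw Bernoulli; a "hard" all-or-nothing mode at the p-value
threshold is available) and otherwise follow a two-piece lognormal that
matches the Bayesian median and both 95% bounds exactly; fup uses the
analogous two-piece logit-normal bounded in (0, 1]; point values use a
default CV of 30%. (4) recalculation of dependent quantities per
individual: tissue partition coefficients from that individual's fup
(`calcpc`), first-pass bioavailability and hepatic clearance
(`firstpass`). Parameters sampled in step 1 but overwritten later
trigger a warning.

With every variance source disabled, each endpoint reduces *exactly* to
its deterministic counterpart (the noMC identity). `calc_mc_css`
evaluates the analytic Css per row (default dose 1 mg/kg/day — the IVIVE
convention) and reports quantiles (default 95th). `calc_mc_oral_equiv`
inverts linearity: dose = target/Css(1 mg/kg/day) at each quantile;
higher-Css individuals need lower external doses, so the 95th percentile
is the health-protective end. `calc_mc_tk` runs full ODE solves over the
sample table and reports per-time mean and sd; failed solves are
excluded and counted.

## Evaluation

RMSLE = sqrt(mean((log10 pred − log10 obs)²)); the per-chemical-first
variant averages squared errors within each chemical before averaging
across chemicals, so data-rich chemicals do not dominate. R² is total
explained variance of predicted vs observed (1 − SSres/SStot), which can
be negative. Zero observed concentrations are floored at a configurable
value before the log transform. `compare_to_observations` groups records
into experimental conditions, simulates each once, interpolates matched-
unit predictions at the observation times (plasma, blood, or exhaled
breath), and reports overall and per-species statistics plus 10-fold /
100-fold error categories and per-species log-log regression lines.

`benchmark_suite` bundles the package-health checks: the count of
steady-state-eligible chemicals, the three unit-ratio identities
((C_mg/L ÷ C_µM)·1000/MW = 1 for the analytic, Monte Carlo, and
full-solve paths), the noMC statistic (RMSLE between Monte Carlo median
Css and the non-varied analytic Css), and optional RMSLE against
user-supplied in vivo or reference steady-state values.

## Synthetic study conditions

`generate_synthetic_library` emulates the marginal spread of a real
screening library: MW lognormal (median 250 g/mol, GSD 1.6), logP
N(2, 1.5), fup logit-normal (median ≈ 0.1, 10% as 3-tuples, 5% recorded
as 0), Clint zero-inflated lognormal (15% non-clearing, 20% as
4-tuples), a volatile fraction with logHenry ~ U(−4, −1) vs U(−10, −6),
30% monoprotic acids and 20% bases, 5% PFAS-tagged, partial coverage of
Rb2p (30%), Caco-2 (50%) and rat data (30%). It does **not** emulate
correlations between properties, assay protocol differences, or
measurement bias, so passing tests establish internal consistency and
correctness of the computational machinery — not predictive accuracy
against real in vivo data, which requires external observation sets.
`generate_synthetic_observations` adds multiplicative lognormal noise to
model-generated concentration-time points; recovering the injected noise
sd through the RMSLE validates the evaluation pipeline end to end.

Problem sizes used by the tests and the acceptance script (50-chemical
library, 100-day steady-state horizon, 200 evaluation conditions,
10²–10³ Monte Carlo draws for endpoint checks and 10⁵ for distribution-
recovery checks) were chosen as the smallest sizes at which the sampling
error of each check is comfortably below its tolerance.

## Numerical choices and degenerate inputs

* Stiff-capable LSODA with per-segment integration between events;
  amounts-based state keeps conservation exact. Degenerate (zero-length)
  segments apply events without integration.
* The steady-state linear solve detects singularity (non-clearing
  chemicals) and negative solutions and raises rather than returning an
  unphysical value.
* Kblood2air above 1e8 (essentially involatile chemicals in the gas
  model) triggers an out-of-domain warning.
* ppmv↔molar conversions default to 298.15 K ambient; the blood:air
  partition uses body temperature from the physiology table. Whether
  ambient or body temperature is canonical is genuinely open; both are
  configurable and the defaults documented here.
* Unit conversion is restricted to a closed controlled vocabulary —
  conversion mistakes are the field's historically worst bug class, and
  a free-form parser invites them.

## Known limitations

* The tissue-composition and physiology constants are editable reference
  values, not a curated evidence-graded dataset.
* The partition model ships uncalibrated; absolute Kp accuracy for real
  chemicals depends on a user-supplied calibration.
* No transporter-mediated processes, renal secretion/reabsorption,
  enterohepatic recirculation, saturable (nonlinear) kinetics, or
  maternal-fetal transfer.
* The population sampler is parametric, not survey-based; it reproduces
  marginal spreads and a single shared size correlation only.
* The gas model's mucus compartment constants are order-of-magnitude
  stand-ins pending airway-specific data.
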