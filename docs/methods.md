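# Methods

This note documents the models implemented in `cardiotwin`, the defaults
and their provenance, the numerical choices, what the synthetic-data
generators do and do not emulate, and the package's known limitations.

## PBPK model

### Structure

The parent drug (amitriptyline, AT) is described by a perfusion-limited
full-PBPK leg: venous blood → lung → arterial blood in series, all other
tissues perfused in parallel from the arterial pool and draining to the
venous pool. Tissue balances are

    V_t dC_t/dt = Q_t (C_art − C_t·BP/Kp_t)

with tissue:plasma partition coefficients `Kp_t` and blood:plasma ratio
`BP`. No portal-vein loop is modeled: gut and spleen drain to the venous
pool like other tissues, and hepatic clearance acts on the liver-outflow
blood concentration, `CL_int_h · C_liver·BP/Kp_liver`. A configurable
fraction `fm_metabolite` (default 0.5) of that flux is converted to the
metabolite with mass scaled by `MW_NT/MW_AT`; the rest is eliminated.
Any flow not assigned to a tissue shunts arterial → venous so perfusion is
conserved.

The metabolite (nortriptyline, NT) uses a minimal-PBPK leg: a central
compartment (`V_central`) exchanging with one lumped "rest" compartment
(`V_re`, `Kp_re`, distribution flow `Q_re`), with linear clearance from
central. The metabolite leg has no explicit heart compartment; NT
heart-tissue concentration is reported as NT plasma × `Kp_ht` (partition
equilibrium), consistent with the partition rule used for observed-plasma
cases.

A `lumped` physiology mode collapses the parent side to a single well-mixed
compartment. It exists for minimal configurations and is what the
closed-form (Bateman) oracle in the test suite runs against.

### Oral absorption

Absorption is empirical first-order input with lag. At each dose time plus
the subject's lag, two depots are charged:

* parent depot: `F × Dose`, draining at `ka` into the venous compartment
  (`F` already nets out gut and hepatic first pass);
* metabolite depot: `(MW_NT/MW_AT) × (1 − Fh) × (fa·Fg) × Dose`, draining
  at the same `ka` into the metabolite central compartment, where
  `Fh = F/(fa·Fg)` is the hepatic escape fraction.

This reading turns the printed constant-rate absorption and first-pass
equations into well-posed depot dynamics while preserving their mass
predictions exactly (the first-pass metabolite mass for a 75 mg dose at the
default F and fa·Fg is 26.56 mg, audited by the mass-balance report).
Sampled pairs with `F > fa·Fg` would imply negative first-pass formation
and are jointly rejected and resampled; the count is recorded on the
population object. Gut-wall-formed metabolite is deliberately not added.

### Default parameters

`MW_AT = 277.4`, `MW_NT = 263.384` g/mol; `Kp_ht = 11.77` and
`fu_ht = 0.0012` for AT, `Kp_ht = 35.63` and `fu_ht = 0.001` for NT — these
are published constants. Everything else in
`data/physiology_default.yaml` / `data/compounds_default.yaml` (tissue
volumes and flows, the AT Kp table, clearances, the NT minimal-leg volumes)
is a plausible default chosen once to give literature-consistent kinetics —
AT Vss ≈ 17 L/kg, blood clearance ≈ 27 L/h (plasma t½ ≈ 25 h), single-dose
t_max ≈ 3–4 h, NT t½ ≈ 26 h — and is deliberately config-driven: the engine
makes no claim that these equal any previously published intravenous
parameterization. With the defaults, a 75 mg dose yields an AT C_max of
≈ 42 ng/mL, inside the clinically observed range for that dose.

### Numerics

Internal units are mg, L, h; the I/O boundary is ng/mL (µM = ng/mL ÷ MW,
since ng/mL ≡ µg/L). Two propagation back ends: `lsoda`/`bdf` via
`scipy.integrate.solve_ivp` (rtol 1e-8, atol 1e-10 defaults), and `expm`,
an exact eigendecomposition propagator valid because the system is linear
and time-invariant between dose events (with an `scipy.linalg.expm`
fallback if the state matrix is detected as non-diagonalizable). The two
agree to < 1e-6 relative in the test suite; `expm` is used inside fitting
loops and population runs for speed. Dose events are applied as exact state
jumps at segment boundaries, so no event is smeared by the integrator.
Mass-conservation accumulator states (eliminated, converted) make the
balance audit exact: residuals are at machine precision, tested < 1e-6.

## Population and virtual twins

* `F`: Normal(0.459, 0.093) truncated to [0.33, 0.62] by rejection.
* `fa·Fg`: lognormal, arithmetic mean 0.832, arithmetic CV 0.131,
  untruncated (enterohepatic recirculation motivates values > 1). The CV is
  read as the arithmetic CV of the variate and moment-matched
  (σ = √ln(1+CV²) = 0.13044, µ = ln(0.832) − σ²/2 = −0.19243); reading the
  0.131 as the σ of the log is exposed as a config switch.
* `t_lag`: mean 1.33 h, CV 30%. The distribution family is not prescribed
  anywhere; lognormal was chosen for positivity (truncated normal available
  by flag). One draw per subject, reused across all of that subject's doses.
* Ions defaulted when a record lacks them: K 4.2, Na 140, Ca 2.4 mM
  (normal-physiology extracellular values; configurable).

A virtual twin fixes whatever the case record reports (age, sex, RR, ions,
prior exposure, dose) and samples the remaining absorption parameters from
the population distributions. Demographic covariates beyond the absorption
parameters do not currently rescale organ sizes (fixed physiology, sampled
absorption) — a conservative choice with hooks for more.

## Cardiac exposure and the three case methodologies

Free cardiac concentration is computed two ways, which coincide at
distribution equilibrium (tested to 2%):

* from observed plasma: `C_plasma × Kp_ht × fu_ht`;
* from simulation: simulated heart-tissue total × `fu_ht` — preferred for
  simulated overdoses because early after a large dose the heart is not at
  partition equilibrium with plasma.

Overdose cases dispatch on what the record contains: (1) plasma levels
only → partition rule on the observations, with a missing NT level imputed
as half the AT level; (2) dose + plasma + ECG window → PBPK simulation,
exposure taken at the simulated AT plasma maximum inside the reported ECG
window; (3) dose only → PBPK simulation from the estimated dose (exposure
at the window maximum if a window exists, else the global maximum). A
record claiming prior drug exposure is first brought to steady state under
a 75 mg daily maintenance regimen before the toxic dose.

## Emax concentration–RR model

The printed form of the sigmoid returns RR = 0 at zero concentration,
contradicting the stated meaning of the baseline parameter; the package
default is the corrected decreasing form
`RR0 − (RR0 − RRmax)·Cⁿ/(EC50ⁿ + Cⁿ)` (baseline 995.3 ms at C = 0, 500.8 ms
asymptote — tachycardia at high exposure), with the literal form retained
behind a flag that warns on use. Fitting minimizes the MSE (reported as
RMSE) by simulated annealing — 10⁴ iterations, geometric cooling 0.95 every
100 steps, coordinate-wise Gaussian proposals at 10% of the box width,
initial temperature = starting cost — followed by an L-BFGS-B polish.
Bounds: RR0 ∈ [600, 1400], RRmax ∈ [200, 995], EC50 ∈ [0.01, 10] µM,
n ∈ [0.5, 5]. The annealing schedule details are package choices (none are
prescribed); a 60-restart multistart check finds the same optima to ~1e-9.

When a case lacks a recorded RR, the per-twin RR is the time average of the
Emax curve over the simulated AT plasma profile.

## Fitting machinery

The cost is a time-weighted MSE; "weighted by time" is read as trapezoid
interval-width weights `w_i = (t_{i+1} − t_{i−1})/2`, which de-bias uneven
sampling grids (alternatives `1/t`, `t`, uniform are selectable and the
choice is logged in the result). Multi-analyte pooling normalizes residuals
by each analyte's mean observed concentration so the parent does not
dominate the metabolite. Reported costs are W-RMSE = √W-MSE.

The global stage is CRS2 with local mutation: population 10·(dim+1)
uniform in the box (the start point seeded in), simplex-reflection trials
through the centroid of the best + dim−1 random members, replace-worst
acceptance, and a coordinate-wise random reflection around the best point
when the trial fails. The evaluation budget (default 1500) counts
post-initialization objective calls. The local stage wraps L-BFGS-B with
3-point numeric gradients, 50 iterations, relative tolerance 1e-20, and
never returns a point worse than its start. Population size and the local
mutation constants are the package's choices following the CRS2
literature's conventions.

## Cardiomyocyte stage

The ten Tusscher & Panfilov (2006) human ventricular cell model is
reimplemented from its publication (19 states; epicardial s-gate and
conductances by default, endo/mid variants included). Integration is
forward Euler for voltage and concentrations with exact-exponential
(Rush–Larsen) updates for the 12 gates at dt = 0.02 ms, numba-compiled when
numba is importable. The control epicardial cell paced at 1000 ms gives
APD90 ≈ 308 ms (published ≈ 301 ms, within the 10% acceptance band used in
the tests), correct rate dependence (shorter APD at faster pacing), and a
stable resting potential (< 1 mV drift over 30 s unpaced).

Drug block is quasi-static: the exposure selected by the cardiac-exposure
stage is held constant during a paced run, matching single-time-window
usage; each blocked current's conductance is multiplied by
`∏_analytes 1/(1 + (C_free/IC50)^Hill)`. The shipped
`data/blocks_example.yaml` IC50/Hill values are *examples* in the right
order of magnitude for tricyclics — the true inhibition table used by the
proprietary simulator this stage stands in for is not public, and no
quantitative claim in this package rests on those numbers.

QT is a single-cell surrogate: APD90 of the last paced beat + a fixed 40 ms
depolarization offset (configurable), not a pseudo-ECG measurement. Bazett
(`QT/√(RR/1000)`) and Fridericia corrections are exact arithmetic. The
arrhythmia flag combines an EAD detector (dV/dt > 0.05 mV/ms sustained
≥ 2 ms between −60 and 0 mV after the plateau peak) and repolarization
failure (V > −40 mV at the next stimulus). In practice this cell model is
EAD-resistant: severe repolarization-reserve loss manifests as
repolarization failure rather than classic EADs, and the flag reflects
whichever occurs.

The ten-run case protocol (default seed 1111) holds concentrations and
heart rate fixed and draws per-run lognormal conductance multipliers
(CV 10%, mean 1) — a population-of-models stand-in for the physiological
between-run variability of a population-scale simulator. Runs are
bit-reproducible per seed. Default pacing is 30 beats to quasi-steady
state; APD drift per beat is small at that depth and the acceptance
properties are insensitive to adding more beats. An optional 1-D strand /
pseudo-ECG mode was considered and not built: it is two orders of magnitude
costlier and adds no information to the single-cell endpoints this package
reports.

## Synthetic data: what it does and does not emulate

The trial generator simulates population-*mean* profiles at known
absorption parameters and adds proportional (10% CV default) plus additive
(0.5 ng/mL floor default) Gaussian noise — the structure assumed of
digitized mean concentration data. It does not emulate between-study
population differences, formulation effects, assay limits of
quantification, or metabolizer-phenotype strata. The Emax generator places
40 log-spaced concentrations over 0.01–10 µM with 120.98 ms Gaussian noise
on the RR scale — matching the residual scale of the published fit, not the
actual case-mix of the literature data. Case-record generation draws
exposures straddling the Emax EC50 (≈ 30–1000 ng/mL) so the PD stages are
exercised.

Passing recovery tests therefore demonstrates that the fitting machinery
recovers known parameters under the assumed noise structure — not that the
models are unbiased on real clinical data.

## Recovery experiments (the headline numbers)

`scripts/acceptance.py` runs two experiments, 20 seeds each:

* absorption: three synthetic single-dose trials (25/50/75 mg, both
  analytes, 15 sampling times to 48 h, 10% proportional noise), two-stage
  fit; medians recover ka = 0.24 h⁻¹ and t_lag = 1.33 h to ≈ 1%.
* Emax: 40-point datasets at 120.98 ms noise; medians recover EC50 and RR0
  to a few percent. The sigmoidicity n is the weakest-identified parameter
  at this noise level: its sampling distribution is right-skewed and the
  20-seed median sits ≈ 25% above the generating value — an intrinsic
  property of the estimator under these conditions (a multistart check
  confirms the optimizer reaches the global optimum), within the stated
  ±30% band for that parameter.

## Known limitations

* Disposition defaults are plausible, not a validated parameterization;
  all quantitative PK claims are conditional on the config.
* No mechanistic gut absorption, no enterohepatic recirculation loop
  beyond the untruncated fa·Fg, no CYP-phenotype strata, no pediatric
  scaling.
* The metabolite heart concentration assumes partition equilibrium.
* Single-cell QT surrogate, not a pseudo-ECG; absolute QT/QTc predictions
  depend on the example inhibition table and the 40 ms offset and should
  be read as relative, property-level outputs.
* Circadian variation of heart rate and ions is not modeled.
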