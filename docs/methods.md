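# Methods

## Scope and model structure

`daptopk` models daptomycin exposure as a linear system built from three
layers: a mechanistic clearance decomposition, a reduced compartmental
disposition model, and Monte-Carlo pharmacodynamics on top of the simulated
exposures. The guiding physiology: daptomycin is ~90–93% bound to serum
albumin, confined essentially to plasma and extracellular water
(Vss ≈ 0.1 L/kg), not metabolized by hepatic microsomes, and eliminated
mostly unchanged in urine, with the remainder attributed to biliary
excretion.

### Clearance decomposition

Renal clearance is treated as pure glomerular filtration of unbound drug —
there is no evidence for tubular secretion or reabsorption of daptomycin —
so

    CL_renal = fup × GFR_abs,      CL_total = CL_renal + CL_H,

with `fup` the unbound plasma fraction and `CL_H` a constant first-order
hepatic (biliary) clearance. The secretion and reabsorption terms are kept
in the data structure (set to zero) so the full renal decomposition stays
testable. `CL_H` is *calibrated*, not predicted: it is the remainder after
subtracting the renal term from a reference healthy total clearance. We
anchor the healthy 70-kg adult total clearance to the reference day-5
exposure of the 6 mg/kg once-daily regimen (420 mg / 580 µg·h/mL =
0.7241 L/h), which makes all downstream exposure targets self-consistent.
With the healthy adult fup of 0.08 and a GFR of 120 mL/min/1.73 m² this
puts ~81% of elimination in the renal route. The commonly cited urinary
recovery (~78%) cannot be matched simultaneously with the AUC anchor; the
AUC anchor wins because the package's outputs are exposure predictions.

Renal impairment changes only the `fup × GFR` term: the representative
normalized GFR of the stage replaces the healthy value and fup moves from
0.08 (healthy) through 0.09 (mild) to 0.10 (moderate and worse); `CL_H`
stays frozen. In the elderly renal-impairment cohort the healthy-state fup
is 0.09 rather than 0.08 (lower albumin in old age).

### Renal staging and representative GFR

Stages follow the conventional bands on normalized GFR (healthy ≥ 90, mild
[60, 90), moderate [30, 60), severe [15, 30), ESRD [0, 15)
mL/min/1.73 m²). The band only constrains, and a simulator needs a point
value, so each stage carries a representative normalized GFR: the band
midpoint for impaired stages (75 / 45 / 22.5 / 7.5) and 120 for healthy
adults. These are module-level configuration, and `make_subject` accepts
per-call overrides, because the representative values are the least
constrained inputs in the pipeline: reverse-engineering the published
adult renal-impairment exposures suggests effective severe-stage GFRs near
the bottom of the band and moderate-stage values near the top, but those
back-calculations are mutually inconsistent under a constant `CL_H`, so we
keep the unbiased midpoints as defaults.

Healthy children get an age-appropriate normalized GFR from a sigmoid
maturation curve on postmenstrual age (half-maturation 47.7 weeks, Hill
coefficient 3.4, adult plateau 120 mL/min/1.73 m²): ~90% of adult function
at age 1, ~98% by age 2. Children younger than 1 year are rejected
outright (the drug's label excludes them). Body surface area uses Du Bois
by default (Haycock selectable); height is recovered from weight and BMI
(`sqrt(W/BMI)`) because the study demographics print only those two.

### Pediatric scaling

The renal route scales mechanistically: child `CL_renal` = child fup ×
child absolute GFR (maturation curve × BSA/1.73). The non-renal route
scales by the adult hepatic-to-renal ratio applied to the child's healthy
renal clearance, then freezes across that child's impairment stages. A
consequence worth stating plainly: this rule fixes the renal fraction of
clearance at the adult value (~81%) for every child, so the relative AUC
inflation caused by a given renal stage is *identical across age groups*
(measured ESRD/healthy daily-AUC ratios: 2.005, 2.005, 2.004, 1.952 for
the 12–17, 7–11, 2–6 and 1–2 y reference children). Whole-body PBPK
platforms scale the biliary route on liver physiology instead and produce
age-dependent ratios; see "Known limitations".

### Disposition

A linear two-compartment model with central elimination and zero-order
infusion input, constrained to `Vss = 0.1 L/kg` of body weight. The
per-dose solution is the standard biexponential closed form; multi-dose
profiles are exact superpositions. Two shape parameters remain:

* `central_fraction` (default 0.702825) — fraction of Vss in the central
  compartment; sets the end-of-infusion peak. Calibrated once so the
  simulated day-5 Cmax of the adult 6 mg/kg regimen equals its reference
  value (86.347 µg/mL).
* inter-compartmental clearance `Q` (default 0.357373 L/h at 70 kg,
  allometric weight^0.75 for other sizes) — solved so the healthy-adult
  terminal half-life is 8.5 h, the middle of the reported 8–9 h range.
  The one-compartment floor `ln2·Vss/CL` (~6.7 h for the healthy adult)
  bounds what is achievable; requests below it raise an error.

`calibrate_adult_disposition` re-runs this calibration from scratch
(multiplicative clearance updates against the AUC anchor, Brent's method
on the central fraction against the Cmax anchor, two outer sweeps); the
frozen defaults above are its output and exist so other subjects can be
simulated without re-anchoring. Because the system is linear, exposures
scale exactly with dose; the published predicted adult table embodies the
same linearity (e.g. its 12 mg/kg AUC is twice its 6 mg/kg AUC to 0.04%).

Numerical choices: simulation grid 0.05 h (must resolve the infusion:
step ≤ duration/3, so the peak lands on the grid); AUC by linear-up/
log-down trapezoid; the trough is the concentration at the interval end
(pre-dose convention — the within-interval minimum of a multi-dose profile
is the *previous* trough); the effective half-life is the log-linear slope
of the post-infusion decline within the interval, which for a
two-compartment model is shorter than the terminal half-life; the
accumulation index is the interval AUC relative to the first dose's.
Steady-state attainment (`steady_state_dose_number`) uses the analytic
geometric accumulation of the closed form, not the grid.

For q48h regimens, "daily AUC" (AUC_0–24) is defined as half the
steady-state 48-h interval AUC — the average daily exposure. The source
tables do not say whether their 24-h AUC for q48h regimens is the first or
second day or an average; the averaging convention keeps AUC/MIC indices
comparable across intervals and reproduces the published
healthy-vs-q48h ratio pattern. Single-dose reference rows report AUC to an
unstated last sampling time; they enter the package only as fold-error
records, not as calibration anchors.

## Validation machinery

Fold error = max(observed, predicted)/min(observed, predicted); < 2 is a
pass. The packaged CSVs transcribe the published adult (22 records) and
pediatric (20 records) observed/predicted AUC and Cmax pairs; the
pediatric table's mean fold error evaluates to 1.09, matching the
published summary, which confirms that summary averages AUC and Cmax
records jointly. Fold errors are kept at full precision internally and
rounded to two decimals only when a report is rendered, as in the source
tables.

## Monte-Carlo pharmacodynamics

Inter-individual variability is log-normal and multiplicative on clearance
(CV 25%) and volume (CV 15%), median 1. The source reports no variability
magnitudes; these defaults are conventional population-PK magnitudes for a
renally cleared drug with low distribution volume, and they are arguments,
not constants. Exposures per subject come from the closed form (interval
AUC = dose/CL exactly; troughs from the analytic steady-state
superposition), vectorized over subjects, so the standard n = 10,000 runs
in milliseconds and PTA/CFR estimates carry ~0.5% Monte-Carlo noise.

PTA at a MIC is the fraction of subjects with total-drug daily AUC/MIC at
or above the target (666 MRSA, 143 E. faecium; an unbound-fraction option
is deliberately absent — the total-drug index is the modeled convention).
CFR is the PTA weighted by a MIC frequency distribution on the
doubling-dilution grid 0.125–8 mg/L. The packaged MIC distributions are
*synthetic* presets shaped like surveillance data (MRSA-like: ≥ 90% of
mass at ≤ 0.5 mg/L; E. faecium-like: modal MIC one to two dilutions
higher), because the real surveillance frequencies behind the published
CFR table are not available. CFR values computed here are therefore
qualitative (is the regimen above 90%?), never numeric reproductions.

Safety: steady-state troughs are screened against 24.3 mg/L, the reported
threshold for elevated creatine-phosphokinase; the package reports the
exceedance fraction and a typical-subject flag, nothing more (clinical
monitoring guidance is out of scope).

## The dose-adjustment rule

Baselines are the label regimens for healthy children (cSSSI: 5/7/9/10
mg/kg q24h for 12–17/7–11/2–6/1–2 y; bacteremia: 7/9/12 mg/kg q24h for
12–17/7–11/1–6 y). The rule: mild/moderate — unchanged; severe — same
mg/kg dose, interval extended to 48 h; ESRD — interval 48 h and the dose
walked down in 1 mg/kg steps (floor 4 mg/kg) until the average-daily-AUC
ratio versus the healthy baseline is ≤ 1.8 while CFR(MRSA) ≥ 0.90. If
nothing in the search space satisfies both, the result is returned
explicitly infeasible. The 1.8 threshold is the most interpretive constant
in the package: the published exposure table keeps regimens unchanged up
to a ratio of 1.74 and reduces doses for ratios of 2.13 and above, and 1.8
separates those two groups.

Two honest caveats, both consequences of facts stated above:

1. Because this package's exposure ratios are age-invariant (~2.0 at ESRD
   for every group), the rule reduces every ESRD baseline by one step —
   it cannot keep the older groups' baselines while cutting the younger
   groups' doses by two to four steps, as the published recommendation
   grid does. No single ratio threshold can, at identical ratios.
2. The published grid is not reproducible even from the publication's own
   exposure ratios under this rule: linear dose-scaling of the printed
   ratios stops the 1–2 y ESRD search at 8 mg/kg (2.13 × 8/10 = 1.70 ≤
   1.8), not the published 6, and the 1–6 y bacteremia search at 9 mg/kg,
   not 8. The published choices for the youngest groups are more
   conservative than any AUC-ratio criterion; whatever objective produced
   them is unstated in the source.

The corresponding acceptance test (exact grid reproduction) is therefore
expected to fail on the ESRD cells and is left failing rather than
weakened; the severe-stage cells (interval extension at unchanged dose)
all match.

## Synthetic data

`generate_virtual_trial` draws observations as
`prediction × exp(ε_prop) + ε_add`, floored at zero, with the
proportional term's log-scale SD chosen so its multiplicative factor has
CV `prop_cv` (default 0.15; the factor is median-unbiased, with a mean
offset of σ²/2 ≈ 0.5% at CV 0.1) and `add_sd` defaulting to 0.5 mg/L —
the standard combined residual-error model of population PK. Expected
values equal the noise-free prediction up to that small log-normal offset,
which the unbiasedness test bounds at 2%.

`recover_clearance` is deliberately non-compartmental: dose divided by the
linear-trapezoid AUC of the observations over the final dosing interval
(which must be covered: ≥ 4 samples, starting within 5% of the interval,
ending within 10%). Over 200 seeded trials at 15% proportional error with
an end-of-infusion sample plus hourly sampling, the median relative bias
is under 3% and ≥ 90% of estimates fall within ±15% — the benchmark the
acceptance suite re-runs. No mixed-effects estimation is attempted.

What the synthetic layer does *not* emulate: real assay quantification
limits, sparse clinical sampling designs, model misspecification (the data
generator is the simulator itself), and real MIC surveillance
distributions. Green recovery tests therefore demonstrate internal
consistency of the pipeline, not field performance on clinical data.

## Problem sizes in the shipped tests

Monte-Carlo checks use n = 2,000–10,000 subjects (exact enumeration
cross-checks use n ≤ 100), recovery studies 200 seeded trials, ODE-oracle
comparisons 2–3 dosing intervals at a 0.05 h grid. The full suite runs in
a few seconds; all sizes are keyword arguments, so larger studies are a
call away.

## Design notes

* Stdlib `dataclasses` (frozen, validated in `__post_init__`) rather than
  pydantic: the domain types are small value objects crossing no
  serialization boundary that would earn pydantic's machinery.
* Population samples store the base subject plus multiplier arrays rather
  than materializing thousands of identical `Subject` objects; the
  `subjects` property exists for interface completeness.
* Physicochemical metadata (MW, logP, solubility, pKa, blood-to-plasma
  ratio) ride along in `DrugParameters` as validated constants but do not
  enter the reduced disposition equations; they are there so the parameter
  file is a complete description of the compound.
* The CLI is a thin veneer: every subcommand is a few calls into the
  library, and YAML configs simply pre-populate command options.

## Known limitations

* The reduced disposition model has no organ-level physiology: no
  permeability-limited tissues, no dialysis modeling for ESRD, no
  nonlinear binding or elimination. It is adequate against printed plasma
  AUC/Cmax but cannot produce tissue concentrations.
* The ratio-preserving non-renal scaling makes impairment exposure ratios
  age-invariant (see above) — the main structural divergence from
  whole-body PBPK behavior, and the reason the published ESRD dose grid is
  not reproduced cell-for-cell.
* Under renal impairment the model changes only fup and GFR; published
  whole-body simulations also perturb distribution and produce Cmax
  *decreases* with impairment that a fixed-volume linear model cannot
  mimic.
* Representative per-stage GFRs are assumption-laden defaults; conclusions
  sensitive to them should sweep the bands via the configuration hooks.
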