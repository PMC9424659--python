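# daptopk

Daptomycin exposure and dose-adjustment modeling for patients with renal
impairment, with a focus on children — a reduced, fully scripted
re-implementation of the kind of analysis usually run inside commercial
PBPK platforms. It is written for pharmacometricians and infectious-disease
modelers who want the whole chain — physiology, clearance scaling,
multi-dose simulation, validation, Monte-Carlo pharmacodynamics and dose
recommendation — as an importable, testable Python library.

## The model in brief

Daptomycin is ~90% albumin-bound, confined to plasma and extracellular
water (Vss ≈ 0.1 L/kg), and cleared mostly by glomerular filtration of the
unbound fraction. The package models clearance as

```
CL_renal = fup · GFR          (filtration only; no secretion/reabsorption)
CL_total = CL_renal + CL_H    (CL_H: constant hepatic/biliary route)
```

with `fup` rising from 0.08 (healthy) to 0.10 (moderate impairment and
worse) and `CL_H` calibrated once by subtracting the renal term from a
reference healthy total clearance (420 mg / 580 µg·h/mL = 0.7241 L/h).
Renal impairment rescales only the `fup·GFR` term; pediatric models take
the renal term from the child's own fup × GFR (maturation curve × BSA) and
the non-renal term from the adult hepatic-to-renal ratio.

Disposition is a linear two-compartment model constrained to
Vss = 0.1 L/kg, with its central-volume split and distributional clearance
calibrated to the published healthy-adult day-5 AUC and Cmax and a 8.5 h
terminal half-life. Efficacy is indexed by total-drug AUC/MIC (targets 666
for MRSA, 143 for *E. faecium*) over 10,000-subject Monte-Carlo samples;
steady-state troughs are screened against the 24.3 mg/L
creatine-phosphokinase risk threshold. Details, assumptions and knobs:
[docs/methods.md](docs/methods.md).

## Worked example

```python
import daptopk as dp

adult = dp.make_subject(35, 70, 25.71, dp.RenalFunctionCategory.HEALTHY,
                        dp.Population.ADULT)
drug = dp.DrugParameters.default()
cal = dp.calibrate_adult_disposition(adult, drug)

regimen = dp.DosingRegimen(dose_mg_per_kg=6, interval_h=24,
                           infusion_duration_h=0.5, n_doses=5)
profile = dp.simulate_regimen(adult, drug, cal.cl_total, regimen,
                              disposition=cal.disposition)
m = dp.pk_metrics(profile, regimen, "last")
print(f"AUC {m.auc_interval:.1f}  Cmax {m.cmax:.2f}  trough {m.cmin_ss:.2f}")
```

prints

```
AUC 580.0  Cmax 86.35  trough 5.69
```

the day-5 interval AUC (µg·h/mL) and peak (µg/mL) matching the calibration
anchors, and a steady-state trough far below the 24.3 mg/L safety
threshold. The `examples/` directory has one short script per capability:

| script | shows |
| --- | --- |
| `01_clearance_scaling.py` | clearance split, impairment rescaling, pediatric scaling |
| `02_simulate_profile.py` | calibration + multi-dose simulation + PK metrics |
| `03_validate_predictions.py` | fold-error validation against the packaged reference tables |
| `04_pta_cfr.py` | Monte-Carlo PTA/CFR and trough safety for a pediatric regimen |
| `05_dose_recommendation.py` | the dose-adjustment rule over the full pediatric grid |
| `06_synthetic_recovery.py` | synthetic trials and non-compartmental clearance recovery |

A thin CLI wraps the same calls
(`daptopk simulate|validate|pta|cfr|recommend|synth`, see `--help`).

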