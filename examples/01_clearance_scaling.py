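"""Clearance decomposition and scaling: adult -> renal impairment -> child.

Builds the healthy 70-kg adult, splits total clearance into renal
(fup x GFR) and non-renal (hepatic/biliary) routes, then shows how the
renal term shrinks with impairment while the hepatic term stays frozen,
and how the model scales to a 5-year-old child.
"""

import daptopk as dp

C = dp.RenalFunctionCategory

adult = dp.make_subject(35, 70, 25.71, C.HEALTHY, dp.Population.ADULT)
# reference total clearance: 420 mg dose over a day-5 interval AUC of 580 ug.h/mL
model = dp.build_clearance_model(adult, dp.cl_from_dose_auc(420, 580))
print(f"healthy adult: CL_renal {model.cl_renal:.3f} + CL_hepatic {model.cl_hepatic:.3f} "
      f"= CL_total {model.cl_total:.3f} L/h")

for cat in (C.MILD, C.MODERATE, C.SEVERE, C.ESRD):
    subj = dp.with_category(adult, cat)
    m = dp.apply_renal_impairment(model, subj)
    print(f"  {cat.value:>8}: GFR {subj.gfr_norm:5.1f} mL/min/1.73m2, fup {subj.fup:.2f} "
          f"-> CL_total {m.cl_total:.3f} L/h (hepatic unchanged: {m.cl_hepatic:.3f})")

child = dp.make_subject(5, 18, 15.68, C.HEALTHY, dp.Population.CHILD)
child_model = dp.scale_to_pediatric(model, adult, child)
print(f"5-y child (18 kg): CL_total {child_model.cl_total:.3f} L/h "
      f"= {1000 * child_model.cl_total / 18:.1f} mL/h/kg "
      f"(vs adult {1000 * model.cl_total / 70:.1f} mL/h/kg) "
      "- per-kg clearance is higher in young children.")
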