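"""Compute maximum safe local-anesthetic doses for a few patients.

Builds three patients of increasing complexity, runs the comprehensive
rule chain (Devine ideal body weight, BMI-gated calculation weight capped
at 70 kg, risk-factor reductions) and prints the dose with its full rule
trace. The mg value is the toxicity ceiling; the mL value is the floored
maximum injectable volume at the configured concentration.
"""

from lasafe import (
    DoseMode,
    PatientRecord,
    Sex,
    load_catalogue,
    max_safe_dose,
)

catalogue = load_catalogue()
ropivacaine = catalogue.get("ropivacaine")

patients = {
    "healthy 80 kg man": PatientRecord(
        age=45, sex=Sex.MALE, height=177.8, actual_weight=80.0
    ),
    "75-year-old with renal dysfunction": PatientRecord(
        age=75, sex=Sex.MALE, height=177.8, actual_weight=80.0, gfr=35.0
    ),
    "obese 65 kg woman (BMI ≥ 30)": PatientRecord(
        age=50, sex=Sex.FEMALE, height=145.0, actual_weight=65.0
    ),
}

for label, patient in patients.items():
    result = max_safe_dose(
        patient, ropivacaine, DoseMode.COMPREHENSIVE, catalogue.cyp_inhibitors
    )
    print(f"\n{label}: max {result.max_mg:.1f} mg ({result.max_ml} mL)")
    for step in result.trace:
        print(f"  {step}")

print(
    "\nEach trace shows which calculation-weight branch fired and which "
    "risk factors reduced the ceiling (one factor −20%, two or more −30%)."
)
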