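# lasafe

Weight-based maximum-safe-dose rules for local anesthetics, and an
evaluation harness for grading dose recommendations against them.

**Research use only: this is an analysis package, not a medical device, and
must not be used for clinical dosing decisions.**

## The problem

Local anesthetics (lidocaine, levobupivacaine, ropivacaine) have a narrow
therapeutic window: exceeding the maximum safe dose risks local anesthetic
systemic toxicity (LAST), with seizures and cardiovascular collapse. The
maximum depends on the patient — body habitus, age, renal, hepatic and
cardiac function, pregnancy, interacting drugs — and on whether two agents
are mixed in one procedure. This package implements a conservative
reference rule set for that maximum, plus the full pipeline used to grade
candidate dose recommendations (for example, answers produced by
general-purpose chatbots) against it, and a synthetic vignette generator so
the whole pipeline is testable end to end.

## The rules

For a patient with actual weight AW (kg), height (cm) and sex:

- **IBW** (ideal body weight, Devine): `50 + 2.3·(inches − 60)` kg for
  males, `45.5 + 2.3·(inches − 60)` for females.
- **BMI** = AW / height(m)².
- **Calculation weight CW**, capped at 70 kg, by exactly one of:
  1. AW ≤ 70, BMI < 30, IBW > AW → CW = AW
  2. AW ≤ 70, BMI < 30, IBW ≤ AW → CW = IBW
  3. AW ≤ 70, BMI ≥ 30 → CW = IBW
  4. AW > 70, IBW > 70 → CW = 70
  5. AW > 70, IBW ≤ 70 → CW = IBW
- **Maximum dose (mg)** = CW × per-drug limit (mg/kg), reduced by 20% if
  one risk factor is present and by 30% if two or more are: age ≥ 70,
  GFR < 50 mL/min, prothrombin time < 50%, LVEF ≤ 30%, pregnancy, or a
  major CYP1A2/3A inhibitor on the medication list.
- **Maximum volume (mL)** = ⌊max mg / concentration⌋. An **overdose** is
  any dose *strictly* exceeding the maximum in its unit. A simplified mode
  (`AW × limit` or `IBW × limit`, no cap, no reductions) supports
  sensitivity analyses. Two-agent mixtures share one fractional toxicity
  budget: component *i* gets proportion *pᵢ* of its own stand-alone
  maximum, with Σ pᵢ = 1.

Per-kg limits are configuration, not constants (shipped literature
defaults: lidocaine 4.5, levobupivacaine 2, ropivacaine 3 mg/kg).

Candidate answers are normalized (ranges → low endpoint, abstentions →
missing) and summarized as: unsafe rate over *provided* answers, percent
exceedance mean/SD (sample SD) over *unsafe* answers, and per-drug
absolute exceedance in each vignette's printed unit. Two-rater 5-point
Likert sheets aggregate by median-then-round (half-up) per criterion,
mean-then-round overall, with Cronbach α for inter-rater reliability.

## Worked example

```python
from lasafe import PatientRecord, Sex, load_catalogue, max_safe_dose

catalogue = load_catalogue()
patient = PatientRecord(age=75, sex=Sex.MALE, height=177.8,
                        actual_weight=80.0, gfr=35.0)
result = max_safe_dose(patient, catalogue.get("ropivacaine"),
                       inhibitor_list=catalogue.cyp_inhibitors)
print(result.max_mg, result.max_ml)
for step in result.trace:
    print(" ", step)
```

prints

```
147.0 19
  BMI=25.3 kg/m², IBW=73.0 kg (Devine), AW=80.0 kg
  CW rule 4 → CW=70.0 kg (cap 70 kg)
  risk factors [age≥70, renal] → ×0.7
  dose limit 3.0 mg/kg → max 147.00 mg
  concentration 7.5 mg/mL → floor 19 mL
```

that is: both actual and ideal weight exceed 70 kg so the calculation
weight is capped at 70 kg; two risk factors (age ≥ 70, GFR 35 < 50) cut
the 210 mg ceiling by 30% to 147 mg, which is at most 19 whole mL of a
7.5 mg/mL solution.

The `examples/` directory has one short script per capability
(reference doses, published-statistics reproduction, synthetic-panel
pipeline, rater agreement). A thin CLI wraps the same functions:

```bash
lasafe compute-dose --patient patients.csv --drug ropivacaine
lasafe simulate --n 10 --profile overdose_prone --seed 42 --out out/
lasafe evaluate --references out/references.csv --responses out/responses.csv --out eval/
lasafe qualitative --sheets sheet.csv
lasafe reproduce-paper --out report/
```

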