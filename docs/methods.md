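# Methods

## Dose model

The reference maximum for a local anesthetic is a conservative,
weight-based ceiling. The chain is: Devine ideal body weight (IBW) and BMI
from height, sex and actual weight (AW); a calculation weight (CW) chosen
by five mutually exclusive branch rules on (AW, IBW, BMI) and capped at
70 kg; a base maximum CW × per-kg limit; and a multiplicative risk
reduction (×0.8 for one factor, ×0.7 for two or more) over six factors —
age ≥ 70 years, glomerular filtration rate < 50 mL/min, prothrombin time
< 50%, left-ventricular ejection fraction ≤ 30%, pregnancy, and major
CYP1A2/3A inhibitors identified by membership in a configurable list (no
interaction inference). Missing organ-function markers mean "not
reported" and contribute no factor; they are never read as zero. Factor
counting is plain: co-occurrence (for example pregnancy with age ≥ 70) has
no special handling beyond the 1-vs-2+ threshold.

The five CW sentences alone are exhaustive and mutually exclusive for
positive inputs (property-tested on a dense grid and against a literal
transcription oracle on 10,000 random triples), but they can exceed 70 kg
on adversarial inputs where IBW is large while AW ≤ 70 and BMI ≥ 30 —
anatomically inconsistent triples that a real patient cannot produce, yet
representable when CW is computed from raw numbers. The explicit
min(·, 70) cap makes the stated invariant CW ≤ 70 unconditional.

All dose arithmetic is double precision; mg values are never rounded.
The only rounding in the model is the conversion to a maximum volume,
⌊max mg / concentration⌋, because syringes are graduated in whole mL and
flooring is the safe direction. A dose is an overdose only when it
*strictly* exceeds the maximum in its unit: a candidate exactly equal to
the ceiling is safe. Threshold comparisons sit exactly as stated (BMI < 30
vs ≥ 30, AW ≤ 70 inclusive, GFR and PT strict <, LVEF inclusive ≤).

Devine constants are the standard published ones (male 50 kg, female
45.5 kg at 60 inches, +2.3 kg/inch; 1 inch = 2.54 cm). Below 152.4 cm the
line is extrapolated downward (IBW may drop below the base constant) with
a logged warning; below 130 cm the formula is outside its validated range
and the input is rejected rather than silently producing nonsense.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| lidocaine limit | 4.5 | mg/kg | common literature maximum, plain solution |
| levobupivacaine limit | 2.0 | mg/kg | common literature maximum |
| ropivacaine limit | 3.0 | mg/kg | common literature maximum |
| concentrations | 10 / 5 / 7.5 | mg/mL | lidocaine 1%, levobupivacaine 0.5%, ropivacaine 0.75% — common preparations |
| CW cap | 70 | kg | hard safety cap of the rule set |
| risk reductions | 0.8 / 0.7 | — | one factor / two-or-more factors |

Per-kg limits and the inhibitor list are deliberately configuration
(YAML), not code constants: institutions differ, and making them explicit
prevents hidden assumptions. Loading without an explicit catalogue path
falls back to the packaged defaults with a logged warning.

Mixtures use fractional additive toxicity: component *i* of a plan with
budget proportions pᵢ (Σpᵢ = 1) receives pᵢ × its own stand-alone maximum,
so the budget shares sum exactly to one. This is the standard clinical
convention for combining agents with additive toxicity; no published
combination rule was available to copy, so the proportions are an explicit
user input rather than an inferred quantity.

## Evaluation conventions

Ranges are reduced to their low endpoint before grading (the most
favorable reading of a range answer); abstentions are missing and leave
the denominator. Unsafe rate = unsafe / provided × 100. Exceedance
statistics (mean and sample SD, n−1) are computed over unsafe cases only;
with a single unsafe case the SD is reported absent, and with none both
moments are absent rather than zero. Per-drug absolute exceedance pools
each case's (candidate − reference) in the vignette's *printed* unit, so
mg and mL cases of the same drug average together numerically. That
convention is what the source study's per-drug numbers use — it is the
only reading that reproduces them — and it is kept as the default for
reproduction, with a unit-consistent alternative (convert via
concentration) available through `ReferenceDose` values expressed in one
unit. Reported rates and statistics round half-up to integers; internal
values stay unrounded.

For qualitative sheets, the per-criterion consensus of two raters is the
median rounded to the nearest integer; a one-level disagreement yields a
half-integer, rounded half-up (toward the better rating) by default with a
half-even switch for sensitivity analysis. The overall label is the
unweighted mean of the criterion consensus values, rounded the same way —
the minimal reading of "an overall value", and it reproduces the published
overall labels. Cronbach α treats the two raters as the test components
and the criteria as observations, k/(k−1)·(1 − Σ var(raterᵢ)/var(sums))
with sample variances; zero total variance raises an explicit error
instead of returning a value.

## Synthetic panels

The generator emulates the *structure* of the study's vignettes, not their
content: adult surgical patients (age 18–90, height 145–200 cm, weight
40–140 kg, sex 1:1 — plausible ranges chosen once; no distributions are
published), per-factor risk planting at a configurable prevalence
(default 0.15), single-agent and two-agent questions, mg and mL framing.
For n ≥ 10 the first ten vignettes deterministically cover all five CW
rules, 0/1/2+ risk factors, both units and both mixture settings
(rejection-sampling patients into each CW branch); smaller panels warn and
generate best-effort. Narrative text is template-rendered and cosmetic —
all computation reads the structured record.

Simulated respondents answer reference × bias, where the bias distribution
places mass above 1 (an overdose by construction) with a configurable
probability; they abstain, emit ranges (low endpoint = value) and flip
units at configurable rates. Because the generator records its own safety
label per answer, the evaluation pipeline can be checked label-by-label:
with unit confusion off the labels must agree exactly, and with it on,
disagreements may occur only on flipped cases. Passing these checks shows
the pipeline is internally consistent at scale; it says nothing about how
real patients or real chatbot answers are distributed, and the shipped
study table remains the only real-data ground truth in the package.

Everything is seeded: the same seed and configuration reproduce panels,
responses and reports byte-for-byte.

## Problem sizes

The recovery analyses (overdose-rate, abstention-rate and label-agreement
checks) use 1000-vignette panels, large enough that three binomial
standard errors are a few percent; the reproduction analyses operate on
the ten published vignettes. Both complete in well under a minute.

## Known limitations

- The published per-vignette reference doses cannot be re-derived from
  the shipped data alone: the original patient details live in
  supplementary material and the per-kg limits behind them are not
  printed. The reference values are therefore fixture inputs, and the
  shipped per-kg limits are labeled defaults.
- The secondary overdose rates under ideal-weight-only and
  actual-weight-only references, and the published inter-rater α = 0.87,
  depend on those same unpublished inputs (vignette details, raw rater
  matrices); the corresponding operations are property-tested rather than
  reproduced.
- One published cell (vignette 9, a mg vignette, value 33.75) is
  anomalous relative to neighboring magnitudes; it is stored verbatim.
- The overdose predicate is one-sided by design: severe *under*-dosing is
  clinically ineffective but never flagged here.
- This package encodes one conservative rule set; it is not clinical
  guidance, and outputs carry a research-use-only disclaimer.
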