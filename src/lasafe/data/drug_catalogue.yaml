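# Local anesthetic catalogue.
#
# dose_limit_mg_per_kg values are literature defaults commonly quoted for
# plain (non-epinephrine) preparations; they are configuration, not study
# constants, and should be reviewed against local institutional guidance.
# concentration_mg_per_ml are common clinical preparations used by the
# synthetic vignette generator (lidocaine 1%, levobupivacaine 0.5%,
# ropivacaine 0.75%).
drugs:
  lidocaine:
    dose_limit_mg_per_kg: 4.5
    concentration_mg_per_ml: 10.0
  levobupivacaine:
    dose_limit_mg_per_kg: 2.0
    concentration_mg_per_ml: 5.0
  ropivacaine:
    dose_limit_mg_per_kg: 3.0
    concentration_mg_per_ml: 7.5

# Major CYP1A2 / CYP3A inhibitors whose presence on a patient's medication
# list counts as a dose-reduction risk factor. Membership check only; no
# interaction inference is performed.
cyp_inhibitors:
  - ciprofloxacin
  - clarithromycin
  - erythromycin
  - azithromycin
  - fluvoxamine
  - ketoconazole
  - itraconazole
  - ritonavir
  - verapamil
  - diltiazem
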