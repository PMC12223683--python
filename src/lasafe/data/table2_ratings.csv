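criterion,gemini,chatgpt,copilot
height_and_weight,poor,poor,poor
age,fair,poor,poor
renal_dysfunction,good,good,fair
hepatic_insufficiency,fair,poor,fair
heart_failure,fair,poor,poor
pregnancy,fair,very poor,very poor
drugs_decreasing_la_metabolism,fair,poor,very poor
use_of_la_mixtures,poor,poor,very poor
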