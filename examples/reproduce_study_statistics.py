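"""Recompute the published chatbot-safety statistics from the shipped table.

Loads the checksummed per-vignette table (reference maxima and the three
chatbots' answers), grades every answer with the strict overdose rule,
and prints each summary statistic next to its published value. A False in
the pass column would mean the pipeline no longer reproduces the study.
"""

from lasafe.reproduction import report_frame, reproduce_results

frame = report_frame(reproduce_results())
print(frame.to_string(index=False))
print(
    f"\n{int(frame['pass'].sum())}/{len(frame)} published statistics "
    "reproduced exactly at the printed precision."
)
print(
    "Rates are over provided answers (abstentions excluded); exceedance "
    "mean/SD are over unsafe answers only, in percent of the reference; "
    "per-drug values are absolute exceedances in each vignette's printed unit."
)
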