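vignette,drug,unit,reference,mixture,gemini,chatgpt,copilot
1,ropivacaine,mg,165,no,150,165,165
2,levobupivacaine,mL,9,yes,15,20.6,10
3,lidocaine,mg,40,yes,,270,270
4,levobupivacaine,mL,18,no,,21,28
5,levobupivacaine,mg,110,no,,240,240
6,ropivacaine,mL,18,yes,,64,
7,levobupivacaine,mg,82.5,no,,120,150
8,lidocaine,mL,6,yes,18.75,33.75,33.75
9,ropivacaine,mg,123.75,no,,270,33.75
10,ropivacaine,mL,29,no,,48,16
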