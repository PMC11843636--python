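# Adverse events previously reported in the sparsentan phase III
# programme (synthetic reconstruction for testing).
Nausea
Fatigue
Nasopharyngitis
Blood creatinine increased
Blood pressure abnormal
Gout
Arthralgia
Pruritus
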