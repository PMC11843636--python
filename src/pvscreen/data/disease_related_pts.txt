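# Preferred terms attributable to IgA nephropathy progression rather
# than to drug exposure (illustrative default; supply your own list).
Proteinuria
Haematuria
Chronic kidney disease
End stage renal disease
Renal failure
Nephropathy
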