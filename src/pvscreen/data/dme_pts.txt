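# Designated Medical Event preferred terms (small synthetic excerpt for
# testing; the EMA publishes the authoritative list).
Agranulocytosis
Stevens-Johnson syndrome
Toxic epidermal necrolysis
Drug reaction with eosinophilia and systemic symptoms
Aplastic anaemia
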