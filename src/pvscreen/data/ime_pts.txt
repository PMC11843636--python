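# Important Medical Event preferred terms (small synthetic excerpt for
# testing; the EMA publishes the authoritative list).
Loss of consciousness
Syncope
Acute kidney injury
Hepatic failure
Seizure
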