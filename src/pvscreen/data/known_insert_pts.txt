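# Adverse events recognized in the sparsentan prescribing information
# (label-derived list; synthetic reconstruction for testing, not the
# verbatim label text).
Anaemia
Oedema peripheral
Blood pressure decreased
Glomerular filtration rate decreased
Hepatic enzyme increased
Blood potassium increased
Dizziness
Hypotension
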