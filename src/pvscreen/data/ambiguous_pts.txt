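# Preferred terms reflecting erroneous or ambiguous reporting usage
# rather than a clinical adverse event (illustrative default).
Drug ineffective
Off label use
Product dose omission issue
Product use issue
Condition aggravated
Therapy interrupted
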