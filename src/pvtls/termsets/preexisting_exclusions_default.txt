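name: preexisting_exclusions_default
scope: pt_narrow
# Default pre-existing-disease exclusion list for the indication-bias
# sensitivity scenario: renal dysfunction and hyperuricemia history terms.
# Extend or replace via configuration.
Renal failure
Renal impairment
Chronic kidney disease
Acute kidney injury
Renal disorder
Hyperuricaemia
Gout
Blood creatinine increased
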