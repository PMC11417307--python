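name: tls_pt_narrow
scope: pt_narrow
# Narrow PT-level definition of tumor lysis syndrome.
Tumour lysis syndrome
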