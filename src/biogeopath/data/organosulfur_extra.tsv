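family_id	max_evalue
DdhA	1e-30
DdhB	1e-30
DdhC	1e-30
Tmm	1e-30
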