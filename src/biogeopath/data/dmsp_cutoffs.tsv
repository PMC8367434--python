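family_id	max_evalue
DSYB	1e-30
DsyB	1e-67
MmtN	1e-98
DmdA	1e-130
DmdB	1e-75
DmdC	1e-100
DmdD	1e-30
AcuH	1e-56
DddD	1e-97
DddK	1e-35
DddL	1e-33
DddP	1e-83
DddQ	1e-20
DddW	1e-49
DddY	1e-64
Alma1	1e-26
DmoA	1e-34
DorA	1e-30
MddA	1e-30
MTO	1e-20
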