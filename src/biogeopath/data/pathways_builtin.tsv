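pathway_id	display_name	cycle	route_index	component_index	families
asr	Assimilatory sulfite reduction (sulfite->sulfide)	sulfur	1	1	K00392
asr	Assimilatory sulfite reduction (sulfite->sulfide)	sulfur	2	1	K00380
asr	Assimilatory sulfite reduction (sulfite->sulfide)	sulfur	2	2	K00381
dnra	Dissimilatory nitrite reduction to ammonia	nitrogen	1	1	K00362
dnra	Dissimilatory nitrite reduction to ammonia	nitrogen	1	2	K00363
dnra	Dissimilatory nitrite reduction to ammonia	nitrogen	2	1	K03385
dnra	Dissimilatory nitrite reduction to ammonia	nitrogen	2	2	K15876
thiosulfate_disproportionation	Thiosulfate disproportionation (thiosulfate->sulfide+sulfite)	sulfur	1	1	phsA
thiosulfate_disproportionation	Thiosulfate disproportionation (thiosulfate->sulfide+sulfite)	sulfur	1	2	phsB
thiosulfate_disproportionation	Thiosulfate disproportionation (thiosulfate->sulfide+sulfite)	sulfur	1	3	phsC
dmsp_synthesis	DMSP biosynthesis (Met->DMSP)	DMSP	1	1	DSYB,DsyB,MmtN
dmsp_demethylation	DMSP demethylation (DMSP->MMPA)	DMSP	1	1	DmdA
mmpa_to_mesh	DMSP demethylation (MMPA->MeSH)	DMSP	1	1	DmdB
mmpa_to_mesh	DMSP demethylation (MMPA->MeSH)	DMSP	1	2	DmdC
mmpa_to_mesh	DMSP demethylation (MMPA->MeSH)	DMSP	1	3	DmdD
mmpa_to_mesh	DMSP demethylation (MMPA->MeSH)	DMSP	2	1	AcuH
dmsp_cleavage	DMSP cleavage (DMSP->DMS)	DMSP	1	1	DddD,DddK,DddL,DddP,DddQ,DddW,DddY,Alma1
dms_to_mesh	DMS oxidation (DMS->MeSH)	DMSP	1	1	DmoA
dms_to_dmso	DMS oxidation (DMS->DMSO)	DMSP	1	1	DdhA
dms_to_dmso	DMS oxidation (DMS->DMSO)	DMSP	1	2	DdhB
dms_to_dmso	DMS oxidation (DMS->DMSO)	DMSP	1	3	DdhC
dms_to_dmso	DMS oxidation (DMS->DMSO)	DMSP	2	1	Tmm
dmso_to_dms	DMSO reduction (DMSO->DMS)	DMSP	1	1	DorA
mesh_to_dms	MddA pathway (MeSH->DMS)	DMSP	1	1	MddA
mesh_oxidation	MeSH oxidation (MeSH->formaldehyde)	DMSP	1	1	MTO
sulfo_emp	Sulfoquinovose degradation, sulfo-EMP	sulfur	1	1	K18479
sulfo_emp	Sulfoquinovose degradation, sulfo-EMP	sulfur	1	2	K18478
sulfo_emp	Sulfoquinovose degradation, sulfo-EMP	sulfur	1	3	K01671
sulfo_emp	Sulfoquinovose degradation, sulfo-EMP	sulfur	1	4	K08318
sulfo_ed	Sulfoquinovose degradation, sulfo-ED	sulfur	1	1	sqDH
sulfo_ed	Sulfoquinovose degradation, sulfo-ED	sulfur	1	2	sglLact
sulfo_ed	Sulfoquinovose degradation, sulfo-ED	sulfur	1	3	sgDehyd
sulfo_ed	Sulfoquinovose degradation, sulfo-ED	sulfur	1	4	kdsgAld
sulfo_ed	Sulfoquinovose degradation, sulfo-ED	sulfur	1	5	slaDH
sft	Sulfoquinovose degradation, SF-transaldolase	sulfur	1	1	K18479
sft	Sulfoquinovose degradation, SF-transaldolase	sulfur	1	2	sfTal
sft	Sulfoquinovose degradation, SF-transaldolase	sulfur	1	3	slaDH
isoprene_degradation	Isoprene degradation (isoprene monooxygenase)	carbon	1	1	IsoA
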