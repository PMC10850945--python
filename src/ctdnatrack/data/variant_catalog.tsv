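gene	protein_change	is_hotspot	is_oncogenic	targetability_level
ESR1	D538G	1	1	none
ESR1	Y537S	1	1	none
ESR1	Y537N	1	1	none
ESR1	Y537C	1	1	none
ESR1	E380Q	1	1	none
ESR1	L536R	1	1	none
ESR1	L536P	1	1	none
ESR1	L536H	1	1	none
ESR1	S463P	1	1	none
PIK3CA	H1047R	1	1	3A
PIK3CA	E545K	1	1	3A
PIK3CA	E542K	1	1	3A
PIK3CA	N345K	1	1	3A
TP53	R175H	1	1	none
TP53	R273H	1	1	none
TP53	R248Q	1	1	none
TP53	Y220C	1	1	none
PTEN	R130G	1	1	4
PTEN	R233*	0	1	4
BRCA1	Q1756*	0	1	2B
BRCA2	W31*	0	1	2B
ERBB2	L755S	1	1	2B
ERBB2	V777L	1	1	2B
BRAF	V600E	1	1	3B
AKT1	E17K	1	1	3B
KRAS	G12D	1	1	none
FGFR2	N549K	1	1	4
EGFR	L858R	1	1	4
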