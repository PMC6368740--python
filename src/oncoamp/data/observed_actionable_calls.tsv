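sample_id	gene	alteration	allele_fraction	cohort
MET_03	ERBB2	Amplification		solid
MET_33	ERBB2	Amplification		solid
MET_39	AKT1	E17K	0.25	solid
MET_18	ERBB2	I654V	0.122222	solid
MET_32	ERBB2	I654V	0.461731	solid
MET_49	ERBB2	I654V	0.495495	solid
MET_07	ESR1	D538G	0.477717	solid
MET_21	ESR1	D538G	0.335884	solid
MET_28	ESR1	D538G	0.454271	solid
MET_27	ESR1	Y537S	0.376441	solid
MET_22	PIK3CA	E453K	0.444722	solid
MET_10	PIK3CA	E542K	0.106212	solid
MET_21	PIK3CA	E542K	0.501912	solid
MET_41	PIK3CA	E542K	0.073183	solid
MET_49	PIK3CA	E542K	0.467702	solid
MET_08	PIK3CA	E545K	0.204327	solid
MET_34	PIK3CA	E545K	0.0871914	solid
MET_40	PIK3CA	E545K	0.844344	solid
MET_25	PIK3CA	H1047R	0.341171	solid
MET_29	PIK3CA	H1047R	0.180681	solid
MET_32	PIK3CA	H1047R	0.2785	solid
MET_33	PIK3CA	H1047R	0.413998	solid
MET_38	PIK3CA	H1047R	0.384692	solid
MET_44	PIK3CA	H1047R	0.60054	solid
MET_06	PIK3CA	N345K	0.376571	solid
MET_35	PIK3CA	Q546R	0.435484	solid
PR_26	BRAF	G469A	0.52028	solid
MET_34	KRAS	G12D	0.074	solid
MET_22	PTEN	C136Y	0.756233	solid
CF_28_Draw_1	ESR1	D538G	0.0746562	ctdna
CF_28_Draw_5	ESR1	D538G	0.146853	ctdna
CF_22_Draw_1	PIK3CA	H1047R	0.320088	ctdna
CF_22_Draw_2	PIK3CA	H1047R	0.402402	ctdna
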