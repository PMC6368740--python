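gene	alteration	level	drugs
ERBB2	Amplification	1	Lapatinib + trastuzumab; Pertuzumab + trastuzumab; Ado-trastuzumab emtansine; Lapatinib; Trastuzumab
AKT1	E17K	3	AZD5363
ERBB2	I654V	3	Neratinib
ESR1	D538G	3	AZD9496; Fulvestrant
ESR1	Y537S	3	AZD9496; Fulvestrant
PIK3CA	E453K	3	Buparlisib; Serabelisib; Alpelisib + fulvestrant; Copanlisib; GDC-0077; Alpelisib; Taselisib + fulvestrant; Buparlisib + fulvestrant; Taselisib
PIK3CA	E542K	3	Buparlisib; Serabelisib; Alpelisib + fulvestrant; Copanlisib; GDC-0077; Alpelisib; Taselisib + fulvestrant; Buparlisib + fulvestrant; Taselisib
PIK3CA	E545K	3	Buparlisib; Serabelisib; Alpelisib + fulvestrant; Copanlisib; GDC-0077; Alpelisib; Taselisib + fulvestrant; Buparlisib + fulvestrant; Taselisib
PIK3CA	H1047R	3	Buparlisib; Serabelisib; Alpelisib + fulvestrant; Copanlisib; GDC-0077; Alpelisib; Taselisib + fulvestrant; Buparlisib + fulvestrant; Taselisib
PIK3CA	N345K	3	Buparlisib; Serabelisib; Alpelisib + fulvestrant; Copanlisib; GDC-0077; Alpelisib; Taselisib + fulvestrant; Buparlisib + fulvestrant; Taselisib
PIK3CA	Q546R	3	Buparlisib; Serabelisib; Alpelisib + fulvestrant; Copanlisib; GDC-0077; Alpelisib; Taselisib + fulvestrant; Buparlisib + fulvestrant; Taselisib
BRAF	G469A	4	LTT462; BVD-523; KO-947
KRAS	G12D	4	LY3214996; KO-947; GDC-0994
PTEN	C136Y	4	AZD6482 + alpelisib
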