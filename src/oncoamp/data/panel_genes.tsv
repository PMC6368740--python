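gene	cnv_reported
ABL1	1
AKT1	1
AKT3	1
ALK	1
AR	1
ARID1A	1
ATM	1
AURKA	1
AURKB	1
BRAF	1
BRCA1	1
BRCA2	1
CCND1	1
CCNE1	1
CDH1	1
CDK4	1
CDK6	1
CDKN1B	1
CDKN2A	1
CDKN2B	1
CTCF	1
CTNNB1	1
DNAH14	1
EGFR	1
ERBB2	1
ERBB3	1
ERBB4	1
ESR1	1
EZH2	0
FGF19	1
FGFR1	1
FGFR2	1
FGFR3	1
FGFR4	1
FOXA1	1
GATA3	1
GRB7	1
HIST2H2BE	0
HRAS	0
IDH1	0
IGF1R	1
IKBKB	1
IKBKE	1
INPP4B	1
INSR	1
JAK2	1
JAK3	1
JUN	0
KDR	1
KIT	1
KMT2C	1
KRAS	0
MAP2K4	1
MAP3K1	1
MAP3K4	1
MDM2	1
MDM4	1
MET	1
MTOR	1
MYC	1
NCOA3	1
NCOR1	1
NCOR2	1
NF1	0
NOTCH1	1
NRAS	1
PAK1	1
PDGFRA	1
PIK3CA	1
PIK3R1	1
PTCH1	1
PTEN	1
RB1	1
RET	1
RPTOR	1
RUNX1	1
SMO	1
STK11	1
TP53	1
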