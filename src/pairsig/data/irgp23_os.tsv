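#name=irgp23_os
#endpoint=OS
#cutoff_strategy=fixed
#cutoff=-0.674
gene_a	gene_b	coefficient
CD8A	LTBP2	-0.009639653
HSPA1A	LYZ	0.098898359
HSPA1A	GBP2	0.06573857
HSPA1A	LTBP3	0.00106882
ICAM1	PLXNB2	-0.039340917
PSME1	NENF	-0.008677831
ZC3HAV1L	CMTM8	0.037052249
APOBEC3G	IKBKE	-0.511310011
CYBB	SEMA7A	-0.0389128
TRIM5	SOS1	-0.064111635
TNFSF10	STC1	-0.089600117
RNASEL	TRIM22	0.019575179
RARRES3	DDX17	-0.036983795
CD40	BIRC5	-0.008823763
ISG15	NENF	-0.225283963
GNLY	EDNRA	-0.027334821
IRF7	AKT1	-0.035142572
TRIM22	CCL17	-0.270054236
BIRC5	NGFR	0.211653036
GBP2	PLXNA1	-0.031264198
GBP2	SHC4	-0.09011139
PTK2B	LHB	-0.397220258
CD86	IL1RN	-0.018374851
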