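AKT1
APOBEC3G
BIRC5
CCL17
CD40
CD86
CD8A
CMTM8
CYBB
DDX17
EDNRA
GBP2
GNLY
HSPA1A
ICAM1
IKBKE
IL1RN
IRF7
ISG15
LHB
LTBP2
LTBP3
LYZ
NENF
NGFR
PLXNA1
PLXNB2
PSME1
PTK2B
RARRES3
RNASEL
SEMA7A
SHC4
SOS1
STC1
TNFSF10
TRIM22
TRIM5
ZC3HAV1L
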