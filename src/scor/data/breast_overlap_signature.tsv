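gene	GSE1456	GSE2034	GSE2990	GSE3494	GSE7390	GSE11121	GSE12093	NKI295	freq	prognosis	function
CREBL2	1	0	0	1	0	1	0	1	4	good	tumor suppressor
CRIM1	1	0	0	1	0	0	0	1	3	good	
SPARCL1	1	0	0	1	0	0	0	1	3	good	
GLTSCR2	1	0	0	0	1	0	0	1	3	good	tumor suppressor
PDS5B	1	0	0	0	1	0	0	1	3	good	tumor suppressor
CD302	1	0	0	1	0	1	0	0	3	good	
FBLN1	1	0	0	1	0	1	0	0	3	good	tumor suppressor
KIAA0494	1	0	0	1	0	1	0	0	3	good	
N4BP2L1	1	0	0	1	0	1	0	0	3	good	
SPTAN1	0	1	0	1	0	1	0	0	3	good	
CCNB2	1	1	0	1	0	1	0	1	5	poor	proliferation
NUSAP1	1	1	0	1	0	1	0	1	5	poor	proliferation
PRC1	1	1	0	1	0	1	0	1	5	poor	proliferation
RACGAP1	1	1	0	1	0	1	0	1	5	poor	proliferation
STMN1	1	0	0	1	0	1	1	1	5	poor	proliferation
CDKN3	1	1	0	1	0	0	1	1	5	poor	proliferation
KIF23	1	0	0	1	0	1	0	1	4	poor	proliferation
MELK	1	0	0	1	0	1	0	1	4	poor	proliferation
MYBL2	1	0	0	1	0	1	0	1	4	poor	proliferation
PTTG1	1	0	0	1	0	1	0	1	4	poor	proliferation
RAD51	1	0	0	1	0	1	0	1	4	poor	proliferation
SPAG5	1	0	0	1	0	1	0	1	4	poor	proliferation
UBE2C	1	0	0	1	0	1	0	1	4	poor	proliferation
BUB1	1	1	0	0	0	1	0	1	4	poor	proliferation
CCNA2	1	1	0	0	0	1	0	1	4	poor	proliferation
CENPF	1	1	0	0	0	1	0	1	4	poor	proliferation
DLGAP5	1	1	0	0	0	1	0	1	4	poor	proliferation
H2AFZ	1	1	0	0	0	1	0	1	4	poor	
NEK2	1	1	0	0	0	1	0	1	4	poor	proliferation
SQLE	1	0	0	0	0	1	1	1	4	poor	
GINS2	1	1	0	1	0	0	0	1	4	poor	proliferation
RRM2	1	1	0	1	0	0	0	1	4	poor	proliferation
CIAPIN1	1	0	0	1	1	0	0	1	4	poor	
NCAPG	1	0	0	1	0	1	1	0	4	poor	proliferation
MLF1IP	1	1	0	1	1	0	0	0	4	poor	proliferation
CTTN	1	0	1	0	1	0	1	0	4	poor	proliferation
ESPL1	0	1	0	1	0	1	0	1	4	poor	proliferation
ZWINT	0	0	0	1	0	1	1	1	4	poor	proliferation
CCNE2	0	1	0	0	0	1	1	1	4	poor	proliferation
CDC25A	1	0	0	0	0	1	0	1	3	poor	proliferation
EXO1	1	0	0	0	0	1	0	1	3	poor	proliferation
FEN1	1	0	0	0	0	1	0	1	3	poor	proliferation
FOXM1	1	0	0	0	0	1	0	1	3	poor	proliferation
KIF2C	1	0	0	0	0	1	0	1	3	poor	proliferation
MCM6	1	0	0	0	0	1	0	1	3	poor	proliferation
NCAPH	1	0	0	0	0	1	0	1	3	poor	proliferation
ACOT7	1	0	0	1	0	0	0	1	3	poor	
C16orf61	1	0	0	1	0	0	0	1	3	poor	
C20orf24	1	0	0	1	0	0	0	1	3	poor	
CCNB1	1	0	0	1	0	0	0	1	3	poor	proliferation
GOT1	1	0	0	1	0	0	0	1	3	poor	
TACC3	1	0	0	1	0	0	0	1	3	poor	proliferation
DTL	1	1	0	0	0	0	0	1	3	poor	proliferation
KPNA2	1	1	0	0	0	0	0	1	3	poor	proliferation
SHCBP1	1	1	0	0	0	0	0	1	3	poor	proliferation
C16orf80	1	0	0	0	1	0	0	1	3	poor	
COG4	1	0	1	0	0	0	0	1	3	poor	proliferation
SNRPA1	1	0	1	0	0	0	0	1	3	poor	
CDC20	1	0	0	1	0	1	0	0	3	poor	proliferation
DDX39	1	0	0	1	0	1	0	0	3	poor	
DHFR	1	0	0	1	0	1	0	0	3	poor	
KIF20A	1	0	0	1	0	1	0	0	3	poor	proliferation
CIAO1	1	1	0	0	0	1	0	0	3	poor	proliferation
KIAA0101	1	1	0	0	0	1	0	0	3	poor	proliferation
TOP2A	1	0	0	0	0	1	1	0	3	poor	proliferation
TIMM17A	1	1	0	1	0	0	0	0	3	poor	
PPFIA1	1	0	0	1	1	0	0	0	3	poor	
APRT	1	0	1	1	0	0	0	0	3	poor	
NOL3	1	1	1	0	0	0	0	0	3	poor	proliferation
EBP	0	0	0	1	0	1	0	1	3	poor	proliferation
H2AFX	0	0	0	1	0	1	0	1	3	poor	proliferation
KIFC1	0	0	0	1	0	1	0	1	3	poor	proliferation
MAD2L1	0	0	0	1	0	1	0	1	3	poor	proliferation
NDUFS6	0	0	0	1	0	1	0	1	3	poor	
SNRPC	0	0	0	1	0	1	0	1	3	poor	
SPC25	0	0	0	1	0	1	0	1	3	poor	proliferation
AURKA	0	1	0	0	0	1	0	1	3	poor	proliferation
TMPO	0	1	0	0	0	1	0	1	3	poor	proliferation
GTSE1	0	0	0	0	0	1	1	1	3	poor	proliferation
CENPM	0	0	0	1	0	0	1	1	3	poor	proliferation
GINS1	0	1	0	1	0	1	0	0	3	poor	proliferation
KIF11	0	1	0	1	0	1	0	0	3	poor	proliferation
TAF11	0	1	0	1	0	1	0	0	3	poor	
CDC2	0	0	0	1	0	1	1	0	3	poor	proliferation
MKI67	0	0	0	1	0	1	1	0	3	poor	proliferation
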