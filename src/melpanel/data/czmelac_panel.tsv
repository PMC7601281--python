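gene_symbol	risk_class
ACD	HIGH_MODERATE_MELANOMA
BAP1	HIGH_MODERATE_MELANOMA
CDK4	HIGH_MODERATE_MELANOMA
CDKN2A	HIGH_MODERATE_MELANOMA
MITF	HIGH_MODERATE_MELANOMA
POT1	HIGH_MODERATE_MELANOMA
TERF2IP	HIGH_MODERATE_MELANOMA
TERT	HIGH_MODERATE_MELANOMA
AGR3	LOW_MELANOMA
ARNT	LOW_MELANOMA
ASIP	LOW_MELANOMA
CASP8	LOW_MELANOMA
CCND1	LOW_MELANOMA
CDKN2B	LOW_MELANOMA
CLPTM1L	LOW_MELANOMA
FTO	LOW_MELANOMA
HERC2	LOW_MELANOMA
IRF4	LOW_MELANOMA
MC1R	LOW_MELANOMA
MGMT	LOW_MELANOMA
MTAP	LOW_MELANOMA
MX2	LOW_MELANOMA
OBFC1	LOW_MELANOMA
OCA2	LOW_MELANOMA
PARP1	LOW_MELANOMA
PLA2G6	LOW_MELANOMA
SETDB1	LOW_MELANOMA
SLC24A4	LOW_MELANOMA
SLC45A2	LOW_MELANOMA
TERF1	LOW_MELANOMA
TERF2	LOW_MELANOMA
TINF2	LOW_MELANOMA
TYR	LOW_MELANOMA
TYRP1	LOW_MELANOMA
APC	CANCER_SYNDROME
ATM	CANCER_SYNDROME
BARD1	CANCER_SYNDROME
BMPR1A	CANCER_SYNDROME
BRCA1	CANCER_SYNDROME
BRCA2	CANCER_SYNDROME
BRIP1	CANCER_SYNDROME
CDH1	CANCER_SYNDROME
FH	CANCER_SYNDROME
CHEK2	CANCER_SYNDROME
KIT	CANCER_SYNDROME
MET	CANCER_SYNDROME
MSH2	CANCER_SYNDROME
MSH3	CANCER_SYNDROME
MSH6	CANCER_SYNDROME
NBN	CANCER_SYNDROME
NF1	CANCER_SYNDROME
NF2	CANCER_SYNDROME
PALB2	CANCER_SYNDROME
PMS2	CANCER_SYNDROME
POLD1	CANCER_SYNDROME
POLE	CANCER_SYNDROME
PTEN	CANCER_SYNDROME
RAD51C	CANCER_SYNDROME
RAD51D	CANCER_SYNDROME
RB1	CANCER_SYNDROME
RET	CANCER_SYNDROME
SDHA	CANCER_SYNDROME
SDHB	CANCER_SYNDROME
SDHC	CANCER_SYNDROME
SDHD	CANCER_SYNDROME
SMAD4	CANCER_SYNDROME
STK11	CANCER_SYNDROME
TP53	CANCER_SYNDROME
VHL	CANCER_SYNDROME
WRN	CANCER_SYNDROME
WT1	CANCER_SYNDROME
ABLIM1	UNKNOWN_MELANOMA_RISK
APEX1	UNKNOWN_MELANOMA_RISK
ATRN	UNKNOWN_MELANOMA_RISK
AURKA	UNKNOWN_MELANOMA_RISK
BBC3	UNKNOWN_MELANOMA_RISK
BLM	UNKNOWN_MELANOMA_RISK
BRAF	UNKNOWN_MELANOMA_RISK
BRMS1	UNKNOWN_MELANOMA_RISK
CASP10	UNKNOWN_MELANOMA_RISK
CBL	UNKNOWN_MELANOMA_RISK
CCAR2	UNKNOWN_MELANOMA_RISK
CCNH	UNKNOWN_MELANOMA_RISK
CDK10	UNKNOWN_MELANOMA_RISK
CDK7	UNKNOWN_MELANOMA_RISK
CDKN1A	UNKNOWN_MELANOMA_RISK
CDKN1B	UNKNOWN_MELANOMA_RISK
CDKN1C	UNKNOWN_MELANOMA_RISK
CEBPA	UNKNOWN_MELANOMA_RISK
COX8A	UNKNOWN_MELANOMA_RISK
CTLA4	UNKNOWN_MELANOMA_RISK
CTNNB1	UNKNOWN_MELANOMA_RISK
CYP11A1	UNKNOWN_MELANOMA_RISK
CYP17A1	UNKNOWN_MELANOMA_RISK
CYP19A1	UNKNOWN_MELANOMA_RISK
CYP1A1	UNKNOWN_MELANOMA_RISK
CYP1A2	UNKNOWN_MELANOMA_RISK
CYP3A5	UNKNOWN_MELANOMA_RISK
DAB2IP	UNKNOWN_MELANOMA_RISK
DCAF4	UNKNOWN_MELANOMA_RISK
DDB1	UNKNOWN_MELANOMA_RISK
DDB2	UNKNOWN_MELANOMA_RISK
EDNRB	UNKNOWN_MELANOMA_RISK
EGF	UNKNOWN_MELANOMA_RISK
EGFR	UNKNOWN_MELANOMA_RISK
EIF1AX	UNKNOWN_MELANOMA_RISK
EPCAM	UNKNOWN_MELANOMA_RISK
ERBB2	UNKNOWN_MELANOMA_RISK
ERBB4	UNKNOWN_MELANOMA_RISK
ERCC1	UNKNOWN_MELANOMA_RISK
ERCC2	UNKNOWN_MELANOMA_RISK
ERCC3	UNKNOWN_MELANOMA_RISK
ERCC4	UNKNOWN_MELANOMA_RISK
ERCC5	UNKNOWN_MELANOMA_RISK
ERCC6	UNKNOWN_MELANOMA_RISK
ERCC8	UNKNOWN_MELANOMA_RISK
EXOC2	UNKNOWN_MELANOMA_RISK
EZH2	UNKNOWN_MELANOMA_RISK
FANCC	UNKNOWN_MELANOMA_RISK
FANCL	UNKNOWN_MELANOMA_RISK
FANCM	UNKNOWN_MELANOMA_RISK
FAS	UNKNOWN_MELANOMA_RISK
FASLG	UNKNOWN_MELANOMA_RISK
FGFR2	UNKNOWN_MELANOMA_RISK
FGFR4	UNKNOWN_MELANOMA_RISK
FLCN	UNKNOWN_MELANOMA_RISK
FLT1	UNKNOWN_MELANOMA_RISK
FOXP3	UNKNOWN_MELANOMA_RISK
GATA2	UNKNOWN_MELANOMA_RISK
GATA4	UNKNOWN_MELANOMA_RISK
GC	UNKNOWN_MELANOMA_RISK
GNA11	UNKNOWN_MELANOMA_RISK
GNAQ	UNKNOWN_MELANOMA_RISK
GPC3	UNKNOWN_MELANOMA_RISK
GSTM1	UNKNOWN_MELANOMA_RISK
GSTM3	UNKNOWN_MELANOMA_RISK
GSTP1	UNKNOWN_MELANOMA_RISK
GSTT1	UNKNOWN_MELANOMA_RISK
H2AFY	UNKNOWN_MELANOMA_RISK
HRAS	UNKNOWN_MELANOMA_RISK
IDH1	UNKNOWN_MELANOMA_RISK
IDH2	UNKNOWN_MELANOMA_RISK
IFIH1	UNKNOWN_MELANOMA_RISK
IFNA1	UNKNOWN_MELANOMA_RISK
IFNG	UNKNOWN_MELANOMA_RISK
IL10	UNKNOWN_MELANOMA_RISK
IL2RA	UNKNOWN_MELANOMA_RISK
IL4	UNKNOWN_MELANOMA_RISK
IL6	UNKNOWN_MELANOMA_RISK
IL8	UNKNOWN_MELANOMA_RISK
ING4	UNKNOWN_MELANOMA_RISK
KAT6A	UNKNOWN_MELANOMA_RISK
KIAA1967	UNKNOWN_MELANOMA_RISK
KMT2A	UNKNOWN_MELANOMA_RISK
KRAS	UNKNOWN_MELANOMA_RISK
LRIG1	UNKNOWN_MELANOMA_RISK
MAP2K1	UNKNOWN_MELANOMA_RISK
MDM2	UNKNOWN_MELANOMA_RISK
MLH1	UNKNOWN_MELANOMA_RISK
MLH3	UNKNOWN_MELANOMA_RISK
MMP1	UNKNOWN_MELANOMA_RISK
MMP3	UNKNOWN_MELANOMA_RISK
MUTYH	UNKNOWN_MELANOMA_RISK
MYH7B	UNKNOWN_MELANOMA_RISK
NCOA6	UNKNOWN_MELANOMA_RISK
NFKB1	UNKNOWN_MELANOMA_RISK
NFKBIE	UNKNOWN_MELANOMA_RISK
NOD2	UNKNOWN_MELANOMA_RISK
NOTCH3	UNKNOWN_MELANOMA_RISK
NRAS	UNKNOWN_MELANOMA_RISK
PAX5	UNKNOWN_MELANOMA_RISK
PDGFRA	UNKNOWN_MELANOMA_RISK
PIGU	UNKNOWN_MELANOMA_RISK
PIK3CA	UNKNOWN_MELANOMA_RISK
PIK3R1	UNKNOWN_MELANOMA_RISK
PIK3R4	UNKNOWN_MELANOMA_RISK
PMAIP1	UNKNOWN_MELANOMA_RISK
PMS1	UNKNOWN_MELANOMA_RISK
POLH	UNKNOWN_MELANOMA_RISK
POMC	UNKNOWN_MELANOMA_RISK
PPM1D	UNKNOWN_MELANOMA_RISK
PPP6C	UNKNOWN_MELANOMA_RISK
PRF1	UNKNOWN_MELANOMA_RISK
PTGS2	UNKNOWN_MELANOMA_RISK
PTCH1	UNKNOWN_MELANOMA_RISK
PTPN11	UNKNOWN_MELANOMA_RISK
PTPN22	UNKNOWN_MELANOMA_RISK
RAC1	UNKNOWN_MELANOMA_RISK
RAD23A	UNKNOWN_MELANOMA_RISK
RAD23B	UNKNOWN_MELANOMA_RISK
RASEF	UNKNOWN_MELANOMA_RISK
RECQL	UNKNOWN_MELANOMA_RISK
RECQL4	UNKNOWN_MELANOMA_RISK
RHOBTB2	UNKNOWN_MELANOMA_RISK
RUNX1	UNKNOWN_MELANOMA_RISK
SBDS	UNKNOWN_MELANOMA_RISK
SF3B1	UNKNOWN_MELANOMA_RISK
SH2B3	UNKNOWN_MELANOMA_RISK
SLX4	UNKNOWN_MELANOMA_RISK
SMARCB1	UNKNOWN_MELANOMA_RISK
SNX31	UNKNOWN_MELANOMA_RISK
STAG2	UNKNOWN_MELANOMA_RISK
STK19	UNKNOWN_MELANOMA_RISK
SUZ12	UNKNOWN_MELANOMA_RISK
TACC1	UNKNOWN_MELANOMA_RISK
TERC	UNKNOWN_MELANOMA_RISK
TLR3	UNKNOWN_MELANOMA_RISK
TRPM1	UNKNOWN_MELANOMA_RISK
TSC1	UNKNOWN_MELANOMA_RISK
TSC2	UNKNOWN_MELANOMA_RISK
VDR	UNKNOWN_MELANOMA_RISK
XAB2	UNKNOWN_MELANOMA_RISK
XPA	UNKNOWN_MELANOMA_RISK
XPC	UNKNOWN_MELANOMA_RISK
XRCC1	UNKNOWN_MELANOMA_RISK
XRCC3	UNKNOWN_MELANOMA_RISK
ZNF365	UNKNOWN_MELANOMA_RISK
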