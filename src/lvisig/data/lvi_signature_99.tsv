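gene	direction
APOC1	up
UCP2	up
FCGBP	up
APOE	up
YWHAZ	up
FGD3	up
CALML5	up
ANXA1	up
SERPINA3	up
LRRC26	up
FST	up
CDCA5	up
CDC42EP4	up
SGCE	up
MMP11	up
GSTP1	up
DNAJA4	up
CFB	up
SLC44A1	up
NME1	up
HBB	up
ELF3	up
CLIC6	up
STC2	up
PGAP3	up
IL17RB	up
GNAS	up
CXCL14	up
TNS3	up
PTTG1	up
MFAP4	up
HMGB3	up
CYP4X1	up
TXNIP	up
SCD	up
MT1E	up
IDH2	up
DKK3	up
VIM	up
SLC9A3R1	up
NINJ1	up
ISG15	up
KRT7	down
ACTG2	down
S100A4	down
KRT8	down
ANG	down
SELENOM	down
LAPTM4B	down
FOS	down
CCNB2	down
C1S	down
SERPINE2	down
LY6E	down
GAS1	down
COX6C	down
CEBPD	down
SLC40A1	down
MX1	down
HBA2	down
EEF1A2	down
CFD	down
SRPX	down
NOP56	down
HLA-DQA1	down
ERBB2	down
CXCL12	down
SUSD3	down
PITX1	down
MAOA	down
HMGA1	down
CYBRD1	down
TPM2	down
S100P	down
MGP	down
HSPB1	down
DCN	down
UBD	down
SLC52A2	down
NDP	down
IFI27	down
DPYSL2	down
VTCN1	down
SPDEF	down
DUSP1	down
PDGFRL	down
ZBTB20	down
KRT18	down
TM7SF2	down
EEF1B2	down
PLGRKT	down
KRT18P55	down
UBE2C	down
FBLN1	down
PYCARD	down
KRT19	down
UBE2S	down
FCER1A	down
RPL3	down
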