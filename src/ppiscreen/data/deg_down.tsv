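A1BG
A2M
ABHD14B
ACADVL
ACAT1
ACTG1
AGR2
AK3
ALDH2
ANXA2
APOA1
APOA2
ASPN
ATP5B
ATP5D
ATP5F1
ATP5O
BGN
C1QC
C3
CALM1
CALML3
CANX
CFH
CFL1
CKM
CKMT1A
COL15A1
CORO1A
CORO1C
CRYAB
CSTB
CTNND1
CYB5R3
DCN
DDOST
DLD
DYNLL1
ECHS1
EIF3A
EPHX1
ERP29
EVPL
F13A1
FAU
FGB
FGG
FKBP4
GGT5
GLUD1
GOT2
GPD2
GRP94
GSN
GSTP1
H2AFY
HIST1H1C
HNRNPL
HP
HSDL2
HSP90
HSPB1
HSPG2
IARS2
IGHA1
IGHG1
IGKC
IMMT
ITIH2
JUP
KRT19
LAMC1
LGALS3
LGALS3BP
LMAN1
LMAN2
LMNA
LMNB1
LRP1
LTF
LUM
LYZ
MARCKS
MTPN
MYH11
MYH7
MYL2
MYLPF
NDRG2
NDUFA10
NDUFA12
NDUFS2
OGDH
OGN
ORM1
ORM2
PA2G4
PCYOX1
PHB
PHB2
PRDX3
PRELP
PSMB1
PSME2
PYCR1
PYGB
RAN
RPL10
RPL19
RPL23A
RPL9
RPN1
RPS11
RPS15
RPS9
RRBP1
SDHA
SERPINA1
SFN
SLC4A1
SOD1
SOD3
SP140
SPTAN1
SPTBN1
SSR4
TGFBI
TMED10
TNNT3
TPM1
TRIM29
TROVE2
U2AF1
UNC84B
UQCRB
UQCRC1
UQCRC2
VDAC1
VDAC2
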