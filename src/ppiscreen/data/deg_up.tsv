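ACAA1
ACTR2
AKR1C2
ALB
ALDH3A1
ANXA11
ARHGAP1
ARHGDIA
ARHGDIB
ARL1
ARPC4
ATIC
ATP6V1A
BLVRB
C1QBP
CA2
CAND1
CAP1
CAPN2
CAPNS1
CCT6A
CCT7
CDC37
CES1
CFL1
CLIC1
CMPK1
COL12A1
CPSF6
CTSB
CTSC
CYCS
DHX9
ECH1
EEF1D
EEF1G
EEF2
EIF2S1
EIF3F
EIF3H
EIF3I
EIF4A1
EIF5A
ENO1
EPPK1
EPS8L1
ERO1L
FABP5
FBP1
FLOT1
FN1
FSCN1
FTL
FUS
G3BP2
G6PD
GAPDH
GCN1L1
GFAP
GNAI2
GSTP1
HADHA
HIST1H1B
HMGA1
HNRNPA1
HNRNPD
HNRPDL
HSP90B1
HSPD1
IDH1
IMPDH2
ISOC2
KPNB1
LAP3
LCP1
LDHB
LGALS7
LTA4H
MAPRE1
METAP1
MPO
MYL6
NAP1L1
NCL
NDRG1
NDUFA8
NP
PABPC1
PDIA4
PDXK
PFN1
PGAM1
PGK1
PGM1
PLEC1
PLS3
PPA1
PPP2R1A
PRKRA
PRTN3
PSMD11
PSMD13
PSMD2
RAB2A
RAP1B
RPL14
RPL6
RPS15A
S100A16
S100A8
S100A9
SERPINB3
SF3A3
SFPQ
SND1
STAT1
TACSTD2
TAGLN2
TALDO1
TAPBP
TF
TFRC
TKT
TLN1
TPI1
TPT1
TRAP1
TXNDC5
TYMP
USP14
VASP
VCL
WARS
WDR1
XRCC5
YWHAZ
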