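# Human protein-kinase gene symbols (curated starter list, editable).
# Used only to restrict kinase-substrate tables to kinase-kinase edges;
# extend toward the full ~518-member kinome for production analyses.
AAK1
ABL1
ABL2
ACVR1
ACVR1B
ACVR2A
ACVR2B
AKT1
AKT2
AKT3
ALK
AMHR2
ARAF
ATM
ATR
AURKA
AURKB
AURKC
AXL
BLK
BMPR1A
BMPR1B
BMPR2
BMX
BRAF
BRSK1
BRSK2
BTK
BUB1
BUB1B
CAMK1
CAMK1D
CAMK2A
CAMK2B
CAMK2D
CAMK2G
CAMK4
CAMKK1
CAMKK2
CASK
CDC7
CDK1
CDK2
CDK3
CDK4
CDK5
CDK6
CDK7
CDK8
CDK9
CDK12
CDK13
CHEK1
CHEK2
CHUK
CLK1
CLK2
CLK3
CLK4
CSF1R
CSK
CSNK1A1
CSNK1D
CSNK1E
CSNK1G1
CSNK1G2
CSNK1G3
CSNK2A1
CSNK2A2
DAPK1
DAPK2
DAPK3
DDR1
DDR2
DYRK1A
DYRK1B
DYRK2
DYRK3
DYRK4
EEF2K
EGFR
EPHA1
EPHA2
EPHA3
EPHA4
EPHA5
EPHA7
EPHB1
EPHB2
EPHB3
EPHB4
ERBB2
ERBB3
ERBB4
FER
FES
FGFR1
FGFR2
FGFR3
FGFR4
FGR
FLT1
FLT3
FLT4
FRK
FYN
GRK2
GRK3
GRK4
GRK5
GRK6
GSK3A
GSK3B
HCK
HIPK1
HIPK2
HIPK3
IGF1R
IKBKB
IKBKE
ILK
INSR
INSRR
IRAK1
IRAK4
ITK
JAK1
JAK2
JAK3
KDR
KIT
LCK
LIMK1
LIMK2
LRRK2
LYN
MAP2K1
MAP2K2
MAP2K3
MAP2K4
MAP2K5
MAP2K6
MAP2K7
MAP3K1
MAP3K2
MAP3K3
MAP3K4
MAP3K5
MAP3K7
MAP3K8
MAP3K9
MAP3K10
MAP3K11
MAP4K1
MAP4K2
MAP4K3
MAP4K4
MAP4K5
MAPK1
MAPK3
MAPK4
MAPK6
MAPK7
MAPK8
MAPK9
MAPK10
MAPK11
MAPK12
MAPK13
MAPK14
MAPK15
MAPKAPK2
MAPKAPK3
MAPKAPK5
MARK1
MARK2
MARK3
MARK4
MAST2
MATK
MELK
MERTK
MET
MINK1
MKNK1
MKNK2
MST1R
MTOR
MUSK
MYLK
MYLK2
NEK1
NEK2
NEK6
NEK7
NEK9
NLK
NTRK1
NTRK2
NTRK3
OXSR1
PAK1
PAK2
PAK3
PAK4
PAK6
PAK7
PASK
PDGFRA
PDGFRB
PDK1
PDPK1
PHKG1
PHKG2
PIM1
PIM2
PIM3
PKMYT1
PKN1
PKN2
PLK1
PLK2
PLK3
PLK4
PRKAA1
PRKAA2
PRKACA
PRKACB
PRKACG
PRKCA
PRKCB
PRKCD
PRKCE
PRKCG
PRKCH
PRKCI
PRKCQ
PRKCZ
PRKD1
PRKD2
PRKD3
PRKG1
PRKG2
PRKX
PTK2
PTK2B
PTK6
RAF1
RET
RIPK1
RIPK2
RIPK3
ROCK1
ROCK2
ROS1
RPS6KA1
RPS6KA2
RPS6KA3
RPS6KA4
RPS6KA5
RPS6KA6
RPS6KB1
RPS6KB2
SGK1
SGK2
SGK3
SIK1
SIK2
SIK3
SLK
SRC
SRPK1
SRPK2
STK3
STK4
STK10
STK11
STK17A
STK17B
STK24
STK25
STK26
STK38
STK39
SYK
TAOK1
TAOK2
TAOK3
TBK1
TEC
TEK
TESK1
TESK2
TGFBR1
TGFBR2
TLK1
TLK2
TNIK
TNK1
TNK2
TRIB1
TRIB2
TRIB3
TSSK1B
TTBK1
TTBK2
TTK
TXK
TYK2
TYRO3
ULK1
ULK2
ULK3
VRK1
VRK2
WEE1
WNK1
WNK2
WNK3
WNK4
YES1
ZAP70
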