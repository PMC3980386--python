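# cavipath van der Waals radius table, version 1
# element,radius_angstrom
# Bondi (1964) values with common extensions; fallback handled in code.
H,1.20
D,1.20
HE,1.40
LI,1.82
BE,1.53
B,1.92
C,1.70
N,1.55
O,1.52
F,1.47
NE,1.54
NA,2.27
MG,1.73
AL,1.84
SI,2.10
P,1.80
S,1.80
CL,1.75
AR,1.88
K,2.75
CA,2.31
MN,2.05
FE,2.04
CO,2.00
NI,1.63
CU,1.40
ZN,1.39
GA,1.87
GE,2.11
AS,1.85
SE,1.90
BR,1.85
KR,2.02
RB,2.50
SR,2.49
MO,2.10
RU,2.05
PD,1.63
AG,1.72
CD,1.58
IN,1.93
SN,2.17
SB,2.06
TE,2.06
I,1.98
XE,2.16
CS,2.60
BA,2.68
PT,1.75
AU,1.66
HG,1.55
TL,1.96
PB,2.02
BI,2.07
U,1.86
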