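# Chemical component codes treated as crystallographic additives rather than
# biologically meaningful ligands. One 3-letter code per line; '#' starts a
# comment. Waters are always filtered regardless of this list. The list is
# user-replaceable: pass your own file to load_additive_list().
HOH
DOD
WAT
# polyethylene glycols and fragments
PEG
PG4
PGE
PE4
1PE
P6G
2PE
MPG
# cryoprotectants / alcohols
GOL
EDO
MPD
PGO
IPA
EOH
MOH
BU3
# buffers
TRS
EPE
MES
BCT
CAC
IMD
# common salts and small ions
SO4
PO4
NO3
ACT
FMT
CIT
FLC
TLA
MLI
OXL
AZI
SCN
CL
BR
IOD
F
NA
K
MG
CA
ZN
MN
NI
CO
CU
CD
HG
LI
CS
SR
BA
# sugars frequently from cryo buffers
SUC
TRE
GLC
# misc
DMS
BME
NH4
ACY
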