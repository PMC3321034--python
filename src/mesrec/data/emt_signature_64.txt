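# Slug-based EMT (mesenchymal transition) signature: 64 genes, in rank order.
COL11A1
THBS2
COL10A1
COL5A2
INHBA
LRRC15
COL5A1
VCAN
FAP
COL1A1
MMP11
POSTN
COL1A2
ADAM12
COL3A1
LOX
FN1
AEBP1
SULF1
FBN1
ASPN
SPARC
CTSK
TNFAIP6
HNT
EPYC
MMP2
PLAU
GREM1
BGN
OLFML2B
LUM
LOXL2
COL6A3
MXRA5
MFAP5
NUAK1
RAB31
TIMP3
CRISPLD2
ITGBL1
CDH11
TMEM158
SPOCK1
SFRP4
SERPINF1
DCN
C7orf10
COPZ2
NOX4
EDNRA
ACTA2
PDGFRB
RCN3
SNAI2
C1QTNF3
COMP
LGALS1
THY1
PCOLCE
COL6A2
GLT8D2
NID2
PRRX1
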