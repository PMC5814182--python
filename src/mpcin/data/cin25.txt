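# CIN25 chromosomal-instability signature: the 25 genes whose expression
# is most consistently correlated with total functional aneuploidy across
# solid tumors (Carter et al., Nat Genet 2006). Human symbols; matching is
# case-insensitive so mouse orthologs (e.g. Foxm1) resolve directly.
# Edit or replace this file to score a different signature.
TPX2
PRC1
FOXM1
CDC2
TGIF2
MCM2
H2AFZ
TOP2A
PCNA
UBE2C
MELK
TRIP13
CNAP1
MCM7
RNASEH2A
RAD51AP1
KIF20A
CDC45L
MAD2L1
ESPL1
CCNB2
FEN1
TTK
CCT5
RFC4
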