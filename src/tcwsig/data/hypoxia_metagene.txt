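# Bundled 51-gene hypoxia metagene (largely HIF target genes), provided as
# an editable gene-set file. Symbols follow common usage at the time the
# signature was published; verify against your expression matrix annotation
# and edit freely — nothing in the package depends on these exact symbols.
VEGFA
SLC2A1
PGAM1
ENO1
LDHA
TPI1
P4HA1
MRPS17
CDKN3
ADM
NDRG1
TUBB6
ALDOA
MIF
ACOT7
MCTS1
PSRC1
PSMA7
ANLN
TUBA1B
MAD2L2
GPI
TUBA1C
MAP7D1
YKT6
RBM35A
HK2
CTSL2
COL4A6
ANGPTL4
KIF20A
SHCBP1
CORO1C
PLOD1
DDIT4
SEC61G
PVR
GAPDH
BNIP3
CA9
SLC25A32
CHCHD2
KIF4A
LRRC42
PGK1
HIG2
UTP11L
SLC16A1
MRGBP
NP
MRPL15
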