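gene,pathway
IDH1,metabolism
IDH2,metabolism
TP53,p53
CDKN2A,p53
MDM2,p53
RB1,cell cycle
EGFR,RTK signaling
EPHA7,RTK signaling
ALK,RTK signaling
FGFR3,RTK signaling
KRAS,RTK signaling
NRAS,RTK signaling
RNF213,RTK signaling
PIK3CA,PI3K/mTOR
PTEN,PI3K/mTOR
MTOR,PI3K/mTOR
SETD2,chromatin remodeling
ATRX,chromatin remodeling
KMT2D,chromatin remodeling
ARID1A,chromatin remodeling
SMARCA4,chromatin remodeling
CREBBP,chromatin remodeling
TAF1,transcription regulation
MN1,transcription regulation
ATM,DNA repair
BRCA2,DNA repair
PTCH1,hedgehog
APC,wnt
NOTCH1,notch
UBR5,ubiquitin ligase
COL2A1,extracellular matrix
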