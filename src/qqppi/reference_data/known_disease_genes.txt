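YWHAZ
YWHAB
YWHAE
MAPK1
DISC1
APP
VCL
VIM
HSPA1A
IKBKB
YWHAQ
SNCA
SQSTM1
HDAC4
TGFB1
SET
SPTBN1
RAD23A
RPS3
CHUK
DAPK1
IGF1R
IRAK1
CYCS
MAP2K4
SRRM2
PHB
YWHAH
CDC42
PRKCZ
APC
NFKBIA
TSC2
TH
ATP5A1
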