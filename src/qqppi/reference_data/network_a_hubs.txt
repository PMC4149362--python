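YWHAZ
ACTB
ACTG1
YWHAB
YWHAE
MAPK1
MAP3K14
DISC1
APP
VCL
VIM
FTSJ1
HSPA1A
IKBKB
YWHAQ
ARRB2
EEF1A1
SNCA
SQSTM1
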