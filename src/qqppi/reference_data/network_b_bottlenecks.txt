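PRKCZ
APC
SNCA
NFKBIA
IQGAP1
TSC2
IGF1R
HSPA1A
OCRL
PARD3
CLTB
TH
ATP5A1
TUBB
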