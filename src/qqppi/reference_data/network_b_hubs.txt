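YWHAZ
YWHAB
CSNK2A1
CLTC
CDC42
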