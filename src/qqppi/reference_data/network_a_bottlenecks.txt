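HDAC4
TGFB1
STUB1
ANXA2
KPNB1
SET
STX1A
SPTBN1
AXIN1
IQGAP1
RAD23A
RPS3
CHUK
MCL1
DAPK1
PARD3
TJP2
ACTN2
TAF9
IGF1R
CDC25B
IARS
CTNNA1
PTPN3
IRAK1
TFRC
VASP
MAP3K7IP2
ADAM17
CYCS
MAP2K4
WEE1
SF3B1
DSTN
SRRM2
BAG2
C1QBP
PHB
YWHAH
GSN
MARCKS
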