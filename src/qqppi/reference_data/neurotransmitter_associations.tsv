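gene	labels
ARRB2	dopaminergic;adrenergic
STX1A	dopaminergic;serotonergic;glutamatergic;GABAergic
TFRC	dopaminergic
MARCKS	dopaminergic;serotonergic;adrenergic;glutamatergic
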