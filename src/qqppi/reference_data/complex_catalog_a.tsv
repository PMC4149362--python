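id	name	members
351	Spliceosome	CD2BP2;DDX17;NF2;PRPF8;SF3A2;SF3B1;SRRM2;WBP11
149,189	Polybromo and BAF containing complex	ACTB;ACTG1;NF2;SMARCA4;SMARCC1;SMARCC2
5909,5937	Ksr1 complex	MAP2K1;MAPK1;YWHAB;YWHAE;YWHAH;YWHAZ
86,566,778	Nucleosomal methylation activator complex, BAF complex, LARC complex	ACTB;NF2;SMARCA4;SMARCC1;SMARCC2
5614	Emerin complex 32	ACTB;NF2;SMARCC1;SMARCC2;VDR
181,193	Proteasome	APC;APP;PSMC4;PSMD1;PSMD4
3055	Nop56p-associated pre-rRNA complex	EEF1A1;MYB;RPLP0;RPLP1;RPS3
5886,5936	Ksr1 complex	MAP2K1;YWHAB;YWHAE;YWHAH;YWHAZ
1230	WINAC complex	NF2;SMARCA4;SMARCC1;SMARCC2;VDR
1181	C complex spliceosome	PNN;PRPF8;SF3A2;SF3B1;SRRM2
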