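node1	node2	r_control	r_disease	printed_change	complex
CD2BP2	PRPF8	0.182452	0.377959	-0.195506	Spliceosome (ID: 351)
CD2BP2	SF3A2	-0.49456	0.300699	-0.795258	Spliceosome (ID: 351)
CD2BP2	WBP11	0.064197	-0.18898	0.253176	Spliceosome (ID: 351)
PRPF8	SF3A2	-0.09299	-0.01542	-0.07757	Spliceosome (ID: 351)
SF3A2	SF3B1	0.236131	-0.15777	0.393901	Spliceosome (ID: 351)
SF3A2	SRRM2	0.210102	0.531593	-0.321490	Spliceosome (ID: 351)
SF3A2	WBP11	-0.10021	-0.16228	0.062070	Spliceosome (ID: 351)
ACTB	ACTG1	0.344993	0.571264	-0.226271	Polybromo and BAF containing complex (ID: 149, 189)
ACTB	SMARCA4	0.272319	0.085326	0.186992	Polybromo and BAF containing complex (ID: 149, 189)
ACTG1	NF2	-0.2271	0.0839	-0.311	Polybromo and BAF containing complex (ID: 149, 189)
SMARCA4	SMARCC1	-0.32228	-0.2122	-0.110080	Polybromo and BAF containing complex (ID: 149, 189)
SMARCC1	SMARCC2	0.197918	0.250794	-0.052876	Polybromo and BAF containing complex (ID: 149, 189)
MAP2K1	MAPK1	0.705468	0.59637	0.109098	Ksr1 complex (ID: 5909, 5937)
YWHAE	YWHAH	-0.30185	-0.16978	-0.132070	Ksr1 complex (ID: 5909, 5937)
YWHAE	YWHAZ	-0.24657	-0.06473	-0.18184	Ksr1 complex (ID: 5909, 5937)
PSMC4	PSMD1	0.305936	0.155939	0.149996	Proteasome (ID: 181, 193)
PSMC4	PSMD4	0.030223	0.49093	-0.460706	Proteasome (ID: 181, 193)
PSMD1	PSMD4	0.129277	0.429546	-0.300269	Proteasome (ID: 181, 193)
EEF1A1	RPLP1	-0.62308	-0.37849	-0.244589	Nop56p-associated pre-rRNA complex (ID: 3055)
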