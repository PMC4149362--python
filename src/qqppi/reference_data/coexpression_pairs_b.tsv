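node1	node2	r_control	r_disease	printed_change	complex
AMPH	AP2A2	0.895323	0.711618	0.183705	Epsin-clathrin complex (ID: 1228)
AP2A2	AP2M1	0.896811	0.71299	0.183821	Epsin-clathrin complex (ID: 1228)
AP2A2	EPS15	0.680562	0.130673	0.549888	Epsin-clathrin complex (ID: 1228)
AMPH	CLTC	0.835258	0.766836	0.068421	Endocytic coat complex (ID: 5344)
AMPH	DNM1	0.859907	0.771107	0.088799	Endocytic coat complex (ID: 5344)
CLTC	EPS15	0.594193	0.346006	0.248186	Endocytic coat complex (ID: 5344)
CLTC	SYNJ1	0.645271	0.769517	-0.124245	Endocytic coat complex (ID: 5344)
DNM1	EPS15	0.752444	0.283483	0.468961	Endocytic coat complex (ID: 5344)
EPS15	SYNJ1	0.694805	0.449957	0.244848	Endocytic coat complex (ID: 5344)
PSMA1	PSMB2	0.389236	0.512285	-0.123048	Proteasome complex (ID: 181, 191, 192, 193, 194)
PSMA1	PSMB7	0.515788	0.620496	-0.104708	Proteasome complex (ID: 181, 191, 192, 193, 194)
PSMB2	PSMB7	0.102045	0.310781	-0.208735	Proteasome complex (ID: 181, 191, 192, 193, 194)
APC	IQGAP1	-0.61332	-0.33299	-0.280329	APC-IQGAP1-Rac1 complex (ID: 3011), APC-IQGAP1-Cdc42 complex (ID: 3012)
CDC42	IQGAP1	-0.18484	-0.2834	0.098559	APC-IQGAP1-Rac1 complex (ID: 3011), APC-IQGAP1-Cdc42 complex (ID: 3012)
CDC42	PARD3	-0.13129	-0.35908	0.227790	CDC42-Par6c-Par3-Prkcz complex (ID: 804), Tiam1-Par-3-aPKC-zeta complex (ID: 1023)
CDC42	PRKCZ	0.762057	0.706097	0.055960	CDC42-Par6c-Par3-Prkcz complex (ID: 804), Tiam1-Par-3-aPKC-zeta complex (ID: 1023)
PARD3	PRKCZ	-0.13645	-0.44763	0.311180	CDC42-Par6c-Par3-Prkcz complex (ID: 804), Tiam1-Par-3-aPKC-zeta complex (ID: 1023)
CSNK2A1	YWHAB	0.253246	0.672328	-0.419082	Ksr1-CK2-MEK-14-3-3 complex, PDGF treated (ID: 5936)
TH	YWHAB	-0.47327	0.157579	-0.630848	Ksr1-CK2-MEK-14-3-3 complex, PDGF treated (ID: 5936)
TH	YWHAZ	-0.36101	-0.1174	-0.243609	Ksr1-CK2-MEK-14-3-3 complex, PDGF treated (ID: 5936)
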