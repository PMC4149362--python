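id	name	members
1228	Epsin-clathrin complex	AMPH;AP2A2;AP2M1;EPS15;TH
5344	Endocytic coat complex	AMPH;CLTC;DNM1;EPS15;SYNJ1
5345	Endocytic coat complex	AMPH;CLTC;DNM1;SYNJ1;TH
181,191,192,193,194	Proteasome complex	APC;PSMA1;PSMB2;PSMB7;TH
3011,3012	APC-IQGAP1-Rac1 complex, APC-IQGAP1-Cdc42 complex	APC;CDC42;IQGAP1;TH
804,1023	CDC42-Par6c-Par3-Prkcz complex, Tiam1-Par-3-aPKC-zeta complex	CDC42;PARD3;PRKCZ;TH
5936	Ksr1-CK2-MEK-14-3-3 complex, PDGF treated	CSNK2A1;TH;YWHAB;YWHAZ
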