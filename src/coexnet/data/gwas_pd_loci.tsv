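table	study	raw_locus	tokens
3	B50	GBA-SYT11 RAB7L1-NUCKS1 SIPA1L2 ACMSD-TMEM163 STK39 DLG2 TMEM175-GAK-DGKQ BST1 FAM47E-SCARB2 SNCA HLA-DQB1 GPNMB INPP5F DLG2 MIR4697 LRRK2 CCDC62 GCH1 TMEM229B BCKDK-STX1B MAPT RIT2 DDRGK1 FGF20 MMP16 ITGA8	GBA;SYT11;RAB7L1;NUCKS1;SIPA1L2;ACMSD;TMEM163;STK39;DLG2;TMEM175;GAK;DGKQ;BST1;FAM47E;SCARB2;SNCA;HLA-DQB1;GPNMB;INPP5F;MIR4697;LRRK2;CCDC62;GCH1;TMEM229B;BCKDK;STX1B;MAPT;RIT2;DDRGK1;FGF20;MMP16;ITGA8
3	B51	MCCC1 LRRK2 SNCA DLG2	MCCC1;LRRK2;SNCA;DLG2
3	B52	PARK16 BST1 SNCA LRRK2	PARK16;BST1;SNCA;LRRK2
4	B53	SYT11 ACMSD STK39 MCCC1/LAMP3 GAK BST1 SNCA HLA-DRB5 LRRK2 CCDC62/HIP1R MAPT	SYT11;ACMSD;STK39;MCCC1;LAMP3;GAK;BST1;SNCA;HLA-DRB5;LRRK2;CCDC62;HIP1R;MAPT
4	B54	ITPKB IL1R2 SCN3A SATB1 NCKIPSD,CDC71 ALAS1,TLR9, DNAH1,BAP1, PHF7,NISCH, STAB1ITIH3, ITIH4 ANK2, CAMK2D ELOVL7 ELOVL7 ZNF184 CTSB SORBS3, PDLIM2, C8orf58,BIN3 SH3GL2 FAM171A1 GALC COQ7 TOX3 ATP6V0A1, PSMC3IP,TUBG2	ITPKB;IL1R2;SCN3A;SATB1;NCKIPSD;CDC71;ALAS1;TLR9;DNAH1;BAP1;PHF7;NISCH;STAB1ITIH3;ITIH4;ANK2;CAMK2D;ELOVL7;ZNF184;CTSB;SORBS3;PDLIM2;C8ORF58;BIN3;SH3GL2;FAM171A1;GALC;COQ7;TOX3;ATP6V0A1;PSMC3IP;TUBG2
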