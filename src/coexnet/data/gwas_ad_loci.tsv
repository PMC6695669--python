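table	study	raw_locus	tokens
1	B17	CLU PICALM CR1 BIN1 CD2AP EPHA1 MS4A ABCA7	CLU;PICALM;CR1;BIN1;CD2AP;EPHA1;MS4A;ABCA7
1	B18	PFDN1/HBEGF USP6NL/ECHDC3 BZRAP1-AS1 NFIC	PFDN1;HBEGF;USP6NL;ECHDC3;BZRAP1-AS1;NFIC
1	B19	TOMM40 PVRL2 APOE CLU PICALM	TOMM40;PVRL2;APOE;CLU;PICALM
1	B20	TOMM40 APOE PVRL2 APOC1	TOMM40;APOE;PVRL2;APOC1
1	B21	TOMM40–APOE region FBXL7 CACNA2D	TOMM40;APOE;FBXL7;CACNA2D
1	B22	ADAMTS4 HESX1 CLNK CNTNAP2 ADAM10 APH1B KAT8 ALPK2 AC074212.3	ADAMTS4;HESX1;CLNK;CNTNAP2;ADAM10;APH1B;KAT8;ALPK2;AC074212.3
1	B23	COBL SLC10A2	COBL;SLC10A2
1	B24	ABCA7 HMHA1 GRIN3B	ABCA7;HMHA1;GRIN3B
2	B25	CR1 BIN1 INPP5D HLA-DRB1 TREM2 CD2AP NYAP1g EPHA1 PTK2B CLU SPI1h MS4A2 PICALM SORL1 FERMT2 SLC24A4 ABCA7 APOE CASS4 ECHDC3 ACE MEF2C NME8	CR1;BIN1;INPP5D;HLA-DRB1;TREM2;CD2AP;NYAP1G;EPHA1;PTK2B;CLU;SPI1H;MS4A2;PICALM;SORL1;FERMT2;SLC24A4;ABCA7;APOE;CASS4;ECHDC3;ACE;MEF2C;NME8
2	B26	CR1 BIN1 CD2AP EPHA1 CLU MS4A6A PICALM ABCA7 CD33 HLA-DRB5– HLA-DRB1 PTK2B SORL1 SLC24A4- RIN3 DSG2 INPP5D MEF2C NME8 ZCWPW1 CELF1 FERMT2	CR1;BIN1;CD2AP;EPHA1;CLU;MS4A6A;PICALM;ABCA7;CD33;HLA-DRB5;HLA-DRB1;PTK2B;SORL1;SLC24A4;RIN3;DSG2;INPP5D;MEF2C;NME8;ZCWPW1;CELF1;FERMT2
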