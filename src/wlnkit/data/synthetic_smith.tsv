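1	C
2	CC
6	CCCCCC
1U1	C=C
2U2	CC=CC
1UU1	C#C
Q2	CCO
Z1	CN
G1	CCl
E2E	BrCCBr
1VQ	CC(=O)O
QVQ	O=C(O)O
ZV1	CC(N)=O
1V1	CC(C)=O
1VO1	COC(C)=O
2O2	CCOCC
1S1	CSC
1M1	CNC
GH	Cl
QQ	OO
OO	O=O
SCN	N#CS
Z2Z	NCCN
Z2Z &GH	Cl.NCCN
1X	CC(C)(C)C
X	CC(C)(C)C
Y	CC(C)C
1Y2	CCC(C)C
K	C[N+](C)(C)C
Z1VQ	NCC(=O)O
1SW1	CS(C)(=O)=O
ZSWQ	NS(=O)(=O)O
1NW	C[N+](=O)[O-]
WNR	O=[N+]([O-])c1ccccc1
Q1XGG2Y1Q1Z	NCC(CO)CCC(Cl)(Cl)CO
Z1Y1Q2X1QGG	NCC(CO)CCC(Cl)(Cl)CO
QR	Oc1ccccc1
ZR	Nc1ccccc1
GR	Clc1ccccc1
1R	Cc1ccccc1
RV1	CC(=O)c1ccccc1
RVH	O=Cc1ccccc1
L6J	c1ccccc1
L6TJ	C1CCCCC1
L5TJ	C1CCCC1
L66J	c1ccc2ccccc2c1
L C666J	c1ccc2cc3ccccc3cc2c1
L B666J	c1ccc2c(c1)ccc1ccccc12
T6NJ	c1ccncc1
T6N CNJ	c1cncnc1
T6NNJ	c1ccnnc1
T6N DNJ	c1cnccn1
T5MJ	c1cc[nH]c1
T5MNJ	c1cn[nH]c1
T5M CNJ	c1c[nH]cn1
T5OJ	c1ccoc1
T5SJ	c1ccsc1
T6OTJ	C1CCOCC1
T5OTJ	C1CCOC1
T66 BNJ	c1ccc2ncccc2c1
L6V DVJ	O=C1C=CC(=O)C=C1
L55 ATJ	C1CC2CCC1C2
L5TJ A&- AL5TJ	C1CCC2(C1)CCCC2
1-SI-1	C[SiH2]C
T-T665 B6 2AB O KO NUT &TTJ IQ MQ B2N1 &- D6J	CN1CCC23c4c5ccc(O)c4OC2C(O)C=CC3C1C5
T B65 H6 F6 F6 3FGH R AO DU GX PN HU- MTT &TTJ CQ JQ P1	CN1CCC23c4c5ccc(O)c4OC2C(O)C=CC3C1C5
L66J B1	Cc1cccc2ccccc12
T6NJ B1	Cc1ccccn1
1R B1	Cc1ccccc1C
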