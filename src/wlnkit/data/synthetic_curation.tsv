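SCN	N#CS
SCUUN	N#CS
Z2Z & GH	Cl.NCCN
Q2 &&beta form	CCO
L6TJ &&ALPHA	C1CCCCC1
mantrap4	CC(C)=O
1V1 TAUT	CC(C)=O
Q1XGG2Y1Q1Z	NCC(CO)CCC(Cl)(Cl)CO
QVQ	O=C(O)O
ZR	Nc1ccccc1
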