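char	meaning	branches	terminating	locant
space	Separator (locants, ions, ring clauses)		no	no
&	Branch/ring pop; ion separator; aromatic flag		no	no
-	Element code / wide ring size / ring chain		no	no
/	Crossed bond clause		no	no
0	Alkane chain of length n	0	no	no
1	Alkane chain of length n	0	no	no
2	Alkane chain of length n	0	no	no
3	Alkane chain of length n	0	no	no
4	Alkane chain of length n	0	no	no
5	Alkane chain of length n	0	no	no
6	Alkane chain of length n	0	no	no
7	Alkane chain of length n	0	no	no
8	Alkane chain of length n	0	no	no
9	Alkane chain of length n	0	no	no
A	Locant only	0	no	yes
B	Boron	3	no	yes
C	Carbon (full valence, implied unsaturation)	4 exactly	no	yes
D	Open chelate	0	no	yes
E	Bromine	1	yes	yes
F	Fluorine	1	yes	yes
G	Chlorine	1	yes	yes
H	Hydrogen	1	yes	yes
I	Iodine	1	yes	yes
J	Ring closure	0	yes	yes
K	Nitrogen (1+ charge, 4 implied methyls)	4	no	yes
L	Open carbocycle	0	no	yes
M	Secondary amine (NH)	2	no	yes
N	Nitrogen	3	no	yes
O	Oxygen	2	no	yes
P	Phosphorus	3	no	yes
Q	Hydroxyl (OH)	1	yes	yes
R	Benzene	1 (expandable)	no	yes
S	Sulphur	3	no	yes
T	Open heterocycle	0	no	yes
U	Unsaturate bond	0	no	yes
V	Carbonyl (C=O)	2	no	yes
W	Add -oxylate (two =O on the neighbour)	0	no	yes
X	Carbon (4 implied methyls)	4	no	yes
Y	Carbon (3 implied methyls)	3	no	no
Z	Primary amine (NH2)	0	yes	no
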