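position	localization	residues
1	cytosol	Y
5	cytosol	G
7	cytosol	F
8	cytosol	Q
9	cytosol	H
10	cytosol	G
11	cytosol	K
12	cytosol	V
13	cytosol	E
14	cytosol	I
15	cytosol	I
16	cytosol	A
17	cytosol	D
18	cytosol	Q
21	cytosol	N
23	cytosol	T
1	ER	Y
5	ER	G
7	ER	F
8	ER	K
9	ER	N
10	ER	G
11	ER	R
12	ER	V
13	ER	E
14	ER	I
15	ER	I
16	ER	A
17	ER	D
18	ER	Q
21	ER	N
23	ER	I
1	mitochondria	N
5	mitochondria	A
7	mitochondria	M
8	mitochondria	E
9	mitochondria	G
10	mitochondria	K
11	mitochondria	TQV
12	mitochondria	PA
13	mitochondria	KR
14	mitochondria	V
15	mitochondria	L
16	mitochondria	E
17	mitochondria	A
18	mitochondria	E
21	mitochondria	SAM
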