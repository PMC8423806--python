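id	species	phylum	localization	inducibility	clade	accession
sp1_cA	sp1	Synthetica	cytosol	inducible	A	SYN0001
sp1_cB	sp1	Synthetica	cytosol	constitutive	B	SYN0002
sp1_er	sp1	Synthetica	ER	unknown	ER	SYN0003
sp1_mt	sp1	Synthetica	mitochondria	unknown	mito	SYN0004
sp2_cA	sp2	Synthetica	cytosol	inducible	A	SYN0005
sp2_cB	sp2	Synthetica	cytosol	constitutive	B	SYN0006
sp2_er	sp2	Synthetica	ER	unknown	ER	SYN0007
sp2_mt	sp2	Synthetica	mitochondria	unknown	mito	SYN0008
sp3_cA	sp3	Synthetica	cytosol	inducible	A	SYN0009
sp3_cB	sp3	Synthetica	cytosol	constitutive	B	SYN0010
sp3_er	sp3	Synthetica	ER	unknown	ER	SYN0011
sp3_mt	sp3	Synthetica	mitochondria	unknown	mito	SYN0012
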