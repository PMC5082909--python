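chrom	pos	gene	transcript	cdna_change	aa_change	rsid	exac_maf	study_id
5	172661963	NKX2-5	ENST00000329198	c.124G>C	p.Ala42Pro	rs113818864	1.58E-04	C46
14	23886518	MYH7	ENST00000355349	c.4363G>A	p.Glu1455Lys	-	-	C37
14	23888685	MYH7	ENST00000355349	c.3853+7C>T	-	rs45467397	2.29E-03	C26
14	23900793	MYH7	ENST00000355349	c.732+1G>A	-	rs730880850	-	C30
14	23900798	MYH7	ENST00000355349	c.728G>A	p.Arg243His	rs267606910	8.24E-06	C19
14	23901862	MYH7	ENST00000355349	c.488A>C	p.Gln163Pro	-	-	C41
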