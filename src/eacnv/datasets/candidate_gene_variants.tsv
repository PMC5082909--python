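chrom	pos	gene	transcript	cdna_change	aa_change	rsid	exac_maf	study_id
2	179446303	TTN	ENST00000589042	c.66692G>A	p.Arg22231His	rs200971254	3.76E-04	C7
2	179575832	TTN	ENST00000589042	c.28131C>A	p.Asn9377Lys	rs72648997	4.23E-05	C4
2	179664626	TTN	ENST00000589042	c.593_595delAAG	p.Glu198del	rs771898264	1.49E-04	C4
2	203420616	BMPR2	ENST00000374580	c.2228A>G	p.Tyr743Cys	rs148257675	3.30E-05	C18
4	47647166	CORIN	ENST00000273857	c.1889G>A	p.Cys630Tyr	rs373155410	8.25E-06	C47
12	114793401	TBX5	ENST00000310346	c.1493C>A	p.Ser498Tyr	-	-	C45
14	23856987	MYH6	ENST00000356287	c.4505G>A	p.Arg1502Gln	rs199936506	1.81E-04	C14
14	23862177	MYH6	ENST00000356287	c.3195G>C	p.Gln1065His	rs267606904	2.31E-04	C31
17	37821649	TCAP	ENST00000309889	c.37_39delGAG	p.Glu13del	rs397516862	-	C2
17	39921023	JUP	ENST00000310706	c.1100G>T	p.Arg367Leu	-	-	C36
19	11152089	SMARCA4	ENST00000358026	c.4373C>T	p.Thr1458Ile	-	-	C1
19	52941827	ZNF534	ENST00000332323	c.1153C>G	p.His385Asp	rs201395526	5.48E-04	C11
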