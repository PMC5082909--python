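cnv_id	study_id	race	type_label	copy_number	sex	locus	chrom	start	end	printed_size_kb	transcripts	phenodigm_genes	recurrent	validated
2	C12	NHB	Dupl	3	-	8q21.13	8	83573868	83964230	390	CTD-2272D18.1;RP11-653B10.1;RP11-731N10.1	-	True	True
2	C47	Asian	Dupl	3	-	8q21.13	8	83848688	83981829	133	CTD-2272D18.1;RP11-731N10.1	-	True	True
4	C43	NHW	Dupl	3	-	1p36.12	1	21002613	21037639	35	KIF17	-	False	False
5	C4	NHB	Dupl	3	-	1p34.1	1	44195344	44428902	234	ARTN;IPO13;RP11-7O11.3;ST3GAL3	ARTN	False	True
6	C34	NHW	Dupl	3	-	1p34.1	1	46058525	46101490	43	CCDC17;GPBP1L1;NASP	NASP	False	True
7	C43	NHW	Dupl	3	-	2p23.1	2	30656586	30735763	79	LCLAT1	LCLAT1	False	False
8	C22	NHW	Het Del	1	-	2q23.1-24.1	2	149164048	156511426	7347	ARL5A;ARL6IP6;CACNB4;EPC2;FMNL2;GALNT13;KCNJ3;KIF5C;LYPD6;LYPD6B;MBD5;MIR4773-1;MMADHC;NEB;NMI;PRPF40A;RBM43;RIF1;RN7SL124P;RNA5SP107;RND3;RPRM;SNORD56;STAM2;TNFAIP6	CACNB4;EPC2;KCNJ3;KIF5C;MBD5;NEB;RIF1;RND3;TNFAIP6	False	True
9	C20	NHW	Dupl	3	-	2q33.1-33.2	2	203134839	203796988	662	BMPR2;CARF;FAM117B;ICA1L;NOP58;RN7SL40P;RN7SL753P;RP11-686O6.1;RP11-686O6.2;WDR12	BMPR2;FAM117B	False	True
10	C14	NHW	Het Del	1	-	3p26.2	3	3804555	3830671	26	SUMF1	SUMF1	False	False
11	C2	HW	Het Del	1	-	3p21.1	3	53406740	53491422	85	SNORA26	-	False	True
12	C23	NHB	Het Del	1	-	4q13.1	4	60249365	60294193	45	-	-	False	False
13	C47	Asian	Dupl	3	-	4q26	4	120028773	120162705	134	MYOZ2;RP11-455G16.1;USP53	MYOZ2	False	True
14	C10	NHW	Dupl	3	-	4q35.1-35.2	4	187078181	187190810	113	CYP4V2;F11;FAM149A;KLKB1	F11;KLKB1	False	False
15	C34	NHW	Dupl	3	-	5q22.1	5	110417428	110444810	27	CTC-551A13.2;WDR36	WDR36	False	False
17	C13	NHW	Het Del	1	-	6p25.3	6	1831050	2175663	345	GMDS	GMDS	False	False
18	C20	NHW	Dupl	3	-	6q22.1	6	118039508	118237605	198	SLC35F1	-	False	True
19	C6	NHW	Dupl	3	-	6q24.3	6	148005232	148138720	133	RP11-307P5.1;RP11-307P5.2	-	False	False
20	C43	NHW	Het Del	1	-	6q25.1	6	151427385	151655101	228	AKAP12;RN7SKP268;RNU6-1247P;RNU6-300P;RNY4P20;RP1-292B18.4;RP1-297M16.2	AKAP12	False	True
21	C26	NHB	Het Del	1	-	8p23.1	8	9258509	9298347	40	RP11-115J16.2	-	False	True
22	C38	HW	Dupl	3	-	8q11.21	8	48170319	48204412	34	SPIDR	-	False	True
23	C3	NHW	Het Del	1	-	8q21.12	8	79775378	80038602	263	AC009941.1	-	False	False
24	C42	NHB	Het Del	1	-	9p24.1	9	7658764	7889991	231	RP11-77E14.2;TMEM261	-	False	True
25	C34	NHW	Dupl	3	-	10q24.33	10	105157553	105215741	58	CALHM1;CALHM2;PDCD11;RP11-225H22.4;RP11-225H22.7	-	False	True
26	C46	HW	Dupl	3	-	10q25.1	10	108765792	108793878	28	SORCS1	-	False	False
27	C34	NHW	Het Del	1	-	11p13	11	35538329	35611601	73	PAMR1;RP5-945I17.2	-	False	False
28	C15	Asian	Dupl	3	-	11q13.3	11	69239611	69434379	195	AP000439.1;AP000439.2;AP000439.3;AP000439.5	-	False	False
29	C30	HW	Dupl	3	-	12p12.1	12	22608226	22649460	41	C2CD5;RP11-359J14.2	-	False	False
30	C35	NHW	Dupl	3	-	12q13.12	12	50893815	50995674	102	DIP2B	DIP2B	False	False
31	C4	NHB	Dupl	3	-	13q21.32	13	67843475	67900578	57	-	-	False	False
32	C4	NHB	Dupl	3	-	13q22.2	13	76247612	76281850	34	LMO7;RP11-29G8.3	LMO7	False	True
33	C9	NHW	Dupl	3	-	16p13.2	16	9041214	9295696	254	C16orf72;RP11-473I1.10;RP11-473I1.5;RP11-473I1.6;RP11-473I1.9;RP11-77H9.8;USP7	USP7	False	True
34	C36	NHW	Het Del	1	-	16q23.2	16	80245950	80316836	71	RP11-525K10.3	-	False	False
35	C3	NHW	Het Del	1	-	19q13.41	19	52932290	52984708	52	ZNF534;ZNF578	-	False	True
36	C14	NHW	Dupl	3	F	Xp22.33	X	902677	1262175	359	RP11-309M23.1	-	False	False
37	C25	NHW	Dupl	3	F	Xp11.3	X	44381642	44872791	491	DUSP21;FUNDC1;KDM6A;RN7SL291P;RNU6-523P	KDM6A	False	True
38	C42	NHB	Del	0	M	Xq11.1	X	61726006	62027422	301	-	-	False	False
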