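characteristic	category	population_count	case_count	printed_population_pct	printed_case_pct	printed_p
Maternal Age (years)	<20	157085	3	7.8	5.9	0.88
Maternal Age (years)	20-34	1480911	38	73.2	74.5	0.88
Maternal Age (years)	>=35	384744	10	19.0	19.6	0.88
Maternal Race/Ethnicity	Non-Hispanic White	1051561	29	52.1	56.9	0.85
Maternal Race/Ethnicity	Black	361836	8	17.9	15.7	0.85
Maternal Race/Ethnicity	Hispanic	437846	10	21.7	19.6	0.85
Maternal Race/Ethnicity	Asian	135374	4	6.7	7.8	0.85
Maternal Race/Ethnicity	Other	31220	0	1.6	0.0	0.85
Maternal Education (years)	<12	384781	11	19.3	21.6	0.91
Maternal Education (years)	12	594659	15	29.8	29.4	0.91
Maternal Education (years)	>12	1017827	25	51.0	49.0	0.91
Parity	Nulliparous	846801	18	41.9	35.3	0.34
Parity	Multiparous	1176248	33	58.1	64.7	0.34
Maternal Smoking	No	1842757	46	91.1	90.2	0.82
Maternal Smoking	Yes	180292	5	8.9	9.8	0.82
Prepregnancy Maternal BMI (kg/m2)	<18.5	40332	0	4.1	0.0	0.66
Prepregnancy Maternal BMI (kg/m2)	18.5-24.9	523438	14	53.5	56.0	0.66
Prepregnancy Maternal BMI (kg/m2)	25-29.9	182264	6	18.6	24.0	0.66
Prepregnancy Maternal BMI (kg/m2)	>=30	233251	5	23.8	20.0	0.66
Case Sex	Male	1036825	30	51.3	58.8	0.28
Case Sex	Female	986210	21	48.8	41.2	0.28
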