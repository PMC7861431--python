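patient	region	z	ratio_pct	wc_class	ichor_class	tissue_class
P01	CD44	14	63	Amp	Gain	0
P01	ZNF217	7.0	27	Amp	Amp	Gain
P01	15q26.1	6.9	32	Amp	Amp	Amp
P01	VEGFA	5.7	21	Amp	Amp	Gain
P02	CDK6	33	71	Amp	Amp	Amp
P02	CCND1	12	26	Amp	Gain	Amp
P03	EGFR	160	439	Amp	0	Amp
P03	MYC	4.7	11	Gain	Amp	Amp
P04	2q32.1	8.6	21	Amp	Amp	Amp
P05	MYC	28	50	Amp	0	Amp
P06	KLF5	8.1	16	Amp	0	Gain
P07	CCND1	12	24	Amp	0	0
P08	MYC	79	114	Amp	Amp	Gain
P09	KRAS	11	20	Amp	0	Gain
P09	MYC	9.6	18	Amp	Amp	Amp
P11	21q11.2	3.2	5	0	0	0
P13	MYC	12	20	Amp	Amp	0
P33	FGFR2	3.2	6	0	0	0
P37	KDR	3.3	6	0	0	0
P40	CD44	3.7	6	0	0	0
P44	FGFR2	124	382	Amp	Amp	0
P44	CD44	81	317	Amp	Amp	0
P44	KLF5	6.5	20	Amp	Gain	0
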