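group	patient	cin	tissue	wc	ichor	ctdna_fraction_pct	targeted_hit	note
TP	P01	yes	yes	yes	yes	8.4	yes
TP	P02	yes	yes	yes	yes	4.3	yes
TP	P03	yes	yes	yes	yes	4.2	yes
TP	P04	yes	yes	yes	yes	5.2	yes
TP	P05	yes	yes	yes	no	0	yes
TP	P06	yes	yes	yes	yes	3.6	yes
P	P07	no	no	yes	yes	2.8	yes
TP	P08	no	yes	yes	yes	3.5	yes
TP	P09	yes	yes	yes	yes	0	yes
TP	P10	yes	yes	yes	yes	2.5	no
TP	P11	no	yes	yes	yes	7.8	no	a
TP	P12	no	yes	yes	yes	4	no
P	P13	no	no	yes	yes	0	yes
TP	P14	yes	yes	yes	no	0	no
T	P15	yes	yes	no	no	5.5	no
TP	P16	no	yes	yes	no	0	no
TP	P17	yes	yes	yes	no	0	no
N	P18	no	no	no	no	0	no
N	P19	no	no	no	no	0	no
T	P20	yes	yes	no	no	0	no
T	P21	no	yes	no	no	0	no
T	P22	no	yes	no	no	0	no
T	P23	no	yes	no	no	0	no
N	P24	no	no	no	no	0	no
N	P25	no	no	no	no	0	no
T	P26	no	yes	no	no	0	no
N	P27	no	no	no	no	0	no
T	P28	no	yes	no	no	0	no
T	P29	no	yes	no	no	0	no
N	P30	no	no	no	no	0	no
T	P31	no	yes	no	no	0	no
N	P32	no	no	no	no	0	no
N	P33	no	no	no	no	0	no	a
N	P34	no	no	no	no	0	no
T	P35	yes	yes	no	no	0	no
N	P36	no	no	no	no	0	no
N	P37	no	no	no	no	0	no	a
T	P38	yes	yes	no	no	0	no
N	P39	no	no	no	no	0	no
N	P40	no	no	no	no	0	no	a
N	P41	no	no	no	no	0	no
T	P42	no	yes	no	no	0	no
N	P43	no	no	no	no	0	no
P	P44	yes	no	yes	yes	5	yes
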