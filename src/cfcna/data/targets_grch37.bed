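# Targeted-analysis regions, GRCh37/hg19. Reconstructed, NON-AUTHORITATIVE
# approximation of recurrently altered gastro-oesophageal cancer genes and
# cytoband regions; replace with a user BED4 for real analyses.
2	183000000	189000000	2q32.1
4	55944644	56009567	KDR
6	43737946	43754224	VEGFA
7	55086725	55324313	EGFR
7	92234235	92465941	CDK6
7	116312459	116438440	MET
8	128748315	128753680	MYC
10	123237848	123357972	FGFR2
11	35160417	35253949	CD44
11	69455873	69469242	CCND1
12	25358180	25403854	KRAS
13	73629113	73651680	KLF5
15	91700000	94300000	15q26.1
17	37844393	37884915	ERBB2
20	52183609	52299577	ZNF217
21	15300000	17900000	21q11.2
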