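# Stand-in list of eight potentially clinically actionable gastro-oesophageal
# amplification targets, GRCh37/hg19 coordinates; NON-AUTHORITATIVE and
# user-replaceable.
6	43737946	43754224	VEGFA
7	55086725	55324313	EGFR
7	92234235	92465941	CDK6
7	116312459	116438440	MET
10	123237848	123357972	FGFR2
11	69455873	69469242	CCND1
12	25358180	25403854	KRAS
17	37844393	37884915	ERBB2
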