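name	sequence	direction	start_position
5F	TGRTTAAATTCHACHAAYGC	forward	7
8F	ACHAAYGCWAARGANATWGG	forward	19
Ag-3F	AGGTACCCTTTATTTAATTTTTGCT	forward	36
6F	GGWACMCTDTATYTDATNTTTGC	forward	37
9F	GGAACGCTGTACTTAATTTTTGC	forward	37
12F	TTYKCDGGDATGATHGGDACDGC	forward	64
11F	GGDATGATHGGDACDGCHTT	forward	70
4F	ATHGGWACWGCYTTYTCHG	forward	76
COXBOL1-F	GACGGCATTTTCWGTTCTTATTAG	forward	81
10F	AGGAACGCTGTACTTSSTTTTTGC	forward	83
13F	AAYGTWATAATWWCWGCTCATGC	forward	160
COXBOL1-R	GATCATARAAACTWGTATTAAAGTTC	reverse	661
4R	CWCCWCCWCCAGCWGGRTC	reverse	676
5R	GTTGATAWARWATWGGRTC	reverse	694
2eR	CYTCNGGRTGACCRAARAAYC	reverse	724
7R	GCVGCWGTRGARTARGCTCTHGWA	reverse	916
6R	GCNGCWGTYAAYTANGCRC	reverse	917
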