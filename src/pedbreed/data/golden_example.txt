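POPULATION	DEMO
PLOIDY	2
UNKNOWN	-
POSSIBLENULL	?
CONFIRMEDNULL	!
NALLELES	4

PEDIGREE
Name	Mother	Father	yield:Q:mt/ha	pericarp_color:C
A	-	-	6	white
B	-	-	4	red
F1	A	B	5.5	-

MAP	LG1
RM001	0
RM005	25

LOCUS	RM001
A	100	102
B	104	106
F1	100	104

IBD	LG1	0
A	1	1	0	0
B	0	0	1	1
F1	0.5	0.5	0.5	0.5
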