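base	A	T	C	G
A		1.28	1.75	13.47
T	1.63		26.33	0.73
C	1.63	19.26		0.73
G	30.18	1.28	1.75	
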