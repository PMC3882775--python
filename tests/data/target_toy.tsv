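R1	R2	R3	R4	R5	R6	R7	R8
0	1	0	0	0	0	0	0
0	1	0	0	1	0	0	0
0	0	0	1	0	0	1	0
1	0	0	1	0	0	1	0
0	0	0	1	0	0	1	1
1	0	1	0	0	0	1	1
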