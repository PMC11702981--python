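gene	s1	s2
g1	5.1	0.4
g2	3.2	4.8
g3	0.7	2.9
g4	8.4	1.6
g5	2.5	7.3
g6	6.0	3.1
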