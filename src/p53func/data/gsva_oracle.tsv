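gene	s1	s2	s3	s4
g1	2.1	5.3	0.8	3.9
g2	7.4	1.2	6.6	2.8
g3	0.5	3.7	4.4	8.1
g4	6.2	6.9	1.5	0.3
g5	3.3	8.8	2.6	5.0
g6	9.1	0.9	7.7	4.2
g7	1.8	2.4	9.5	6.7
g8	4.6	7.1	3.0	1.1
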