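sample	group	platform	age	coverage	CO	NCO	ambiguous	complex
AA1-s1	sperm	sequel	62	20.0	161	45	95	3
AA1-s2	sperm	sequel	74	16.7	130	31	78	8
AA2-t1	sperm	sequel	24	31.3	262	72	135	45
AA2-t2	sperm	sequel	36	24.2	179	82	110	54
AA3	sperm	sequel	74	31.2	205	73	126	31
AA4	sperm	sequel	47	21.5	180	51	80	24
AA5	sperm	revio	62	53.6	520	233	419	13
AA6	sperm	revio	31	51.8	447	212	326	11
AA7	sperm	revio	32	57.0	501	212	346	18
AA8	sperm	revio	31	49.8	442	171	346	12
AA9	sperm	revio	28	48.8	425	181	346	9
AN-s1	sperm	sequel	27	31.2	233	91	161	62
AN-s2	sperm	sequel	40	24.3	202	71	118	33
AB	sperm	revio	33	40.3	363	149	304	9
AD	sperm	sequel	26	23.7	210	85	119	19
C1	control	sequel	0	70.2	2	20	7	22
C2	control	sequel	82	30.1	2	19	3	2
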