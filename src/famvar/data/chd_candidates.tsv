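chrom	pos	ref	alt	gene	transcript	hgvs_c	hgvs_p	consequence	af_exomes_all	nhomalt	cadd_phred	family	causative
1	1000	C	T	CASZ1	NM_001079843.2	c.73C>T	p.Arg25Cys	missense_variant	0.0007		32.0	16	1
18	2000	A	T	ROCK1	NM_005406.2	c.2083A>T	p.Lys695Ter	stop_gained	0		40.0	154	1
15	3000	A	C	MCTP2	NM_018349.3	c.65A>C	p.Asn22Thr	missense_variant	0.0005		32.7	154	1
11	4000	G	C	ROBO4	NM_019055.5	c.1087G>C	p.Val363Leu	missense_variant	0.0002		22.5	207	1
10	5000	G	A	CTBP2	NM_022802.2	c.2156G>A	p.Arg719His	missense_variant	0.00003		27.8	238	1
2	6000	C	T	SMYD1	NM_198274.3	c.1321C>T	p.Arg441Trp	missense_variant	0.014		33.0	346	1
2	7000	C	T	BMP10	NM_014482.1	c.625C>T	p.Arg209Cys	missense_variant	0.012		26.1	346	1
14	8000	TT	CC	MYH6	NM_002471.3	c.733_734delinsCC	p.Phe245Pro	missense_variant	0			368	1
5	9000	A	T	MATR3	NM_018834.5	c.629A>T	p.Glu210Val	missense_variant	0.000009		23.0	439	1
9	10000	G	A	NOTCH1	NM_017617.4	c.2995G>A	p.Val999Met	missense_variant	0.0003		24.3	469	1
8	11000	C	A	HEY1	NM_012258.3	c.800C>A	p.Ser267Tyr	missense_variant	0.0001		28.7	528	0
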