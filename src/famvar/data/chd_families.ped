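# Sequenced subjects of the 19 multiplex left-sided CHD families.
# 6-column PED + one free-text phenotype label column.
# Parent links are recorded only where the parent is itself a sequenced subject.
16	38	0	39	1	2	HLHS
16	39	0	0	2	2	BAV
19	54	0	0	1	2	BAV
19	55	0	0	1	2	BAV
19	67	0	0	1	2	BAV,COA
58	160	162	0	1	2	HLHS
58	162	0	0	1	2	BAV
58	168	162	0	2	2	ARSA
72	196	0	0	1	2	AVS,BAV
72	199	0	0	1	2	BAV
91	284	286	0	2	2	BAV
91	286	0	0	1	2	BAV
118	376	0	377	2	2	COA
118	377	0	0	2	2	BAV
154	517	0	515	1	2	AVS,BAV
154	515	0	0	2	2	AVS,BAV
154	514	0	515	1	2	AVS,BAV
154	518	0	515	2	2	MildPVabnormality
207	683	0	0	1	2	BAV
207	686	0	0	1	2	BAV,LVNC,AccessoryMV
238	796	0	0	2	2	BAV,VSD,AoRootDilation
238	799	0	0	2	2	BAV,VSD
241	806	0	807	1	2	HLHS
241	807	0	0	2	2	CalcifiedMV
346	1128	0	0	1	2	AVS,BAV
346	1131	0	0	2	2	AVS
368	1197	0	0	2	2	BAV,COA,VSD
368	1698	0	0	1	2	COA
400	1339	1302	0	1	2	COA
400	1302	0	0	1	2	COA
400	1870	0	0	2	2	HLHS
439	1430	1432	0	1	2	AVS
439	1432	0	0	1	2	BAV,COA
469	1529	1531	0	2	2	HLHS
469	1531	0	0	1	2	AVS,BAV
469	1608	1531	0	2	2	AVS
481	1567	0	0	2	2	BAV
481	1571	0	0	1	2	BAV
481	1601	0	0	1	2	AVS,BAV,AoAneurysm
512	1699	1701	0	2	2	HLHS
512	1701	0	0	1	2	PVS
512	1822	1701	0	1	2	DORV,PVatresia,TGA
528	1747	1749	0	2	2	BAV,COA
528	1749	0	0	1	2	BAV
549	1823	0	0	1	2	AS,BAV
549	1826	0	0	1	2	BAV
549	1828	0	0	1	2	AS,BAV
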