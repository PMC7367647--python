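name	chrom	loc.start	loc.end	direction	key_genes	frequency	seg_mean	logP
1p-	chr1	0	145000000	loss		0.6522	-0.49	-100.0
1q+	chr1	145200000	249000000	gain		0.7826	1.3568	-100.0
4-	chr4	0	190800000	loss	DKK2	0.6087	-0.7707	-100.0
6p+	chr6	0	69000000	gain	VEGFA	0.4783	0.7813	-100.0
6q-	chr6	69200000	170800000	loss		0.4783	-0.5582	-100.0
7+	chr7	0	158800000	gain		0.3478	0.335	-100.0
8q+	chr8	43600000	146000000	gain	MYC	0.9130	1.0033	-100.0
10q-	chr10	38600000	135200000	loss	PTEN	0.6087	-0.4361	-69.3
13q-	chr13	19000000	114800000	loss		0.6522	-0.3688	-68.8
8p-	chr8	8000000	43400000	loss	DLC1	0.5217	-0.9049	-62.1
20+	chr20	0	62400000	gain		0.5217	0.4562	-57.1
11q-	chr11	71600000	134800000	loss		0.3913	-0.4313	-55.9
11p-	chr11	0	68200000	loss		0.4348	-0.4535	-46.3
16-	chr16	0	90000000	loss		0.4348	-0.4275	-45.5
9-	chr9	0	141000000	loss		0.4783	-0.2474	-38.1
17p-	chr17	0	19800000	loss	TP53	0.5217	-0.8408	-35.4
21q-	chr21	9400000	47800000	loss		0.3043	-0.4427	-29.1
14q-	chr14	19000000	107000000	loss		0.4348	-0.2948	-27.1
10p+	chr10	200000	35600000	gain		0.3043	0.318	-23.8
3-	chr3	0	197800000	loss		0.2174	-0.1392	-23.1
18-	chr18	0	77800000	loss		0.2609	-0.1713	-14.3
TERT+	chr5	0	5800000	gain	TERT	0.3913	0.7377	-12.8
8pter-	chr8	0	6800000	loss		0.3478	-0.7036	-12.2
10cen+	chr10	35800000	38400000	gain		0.2174	1.1605	-8.2
15q+	chr15	20000000	102200000	gain		0.1739	0.119	-7.4
17q+	chr17	20000000	80800000	gain		0.3913	0.1189	-6.3
19+	chr19	0	58800000	gain		0.0870	0.123	-5.6
CCND1+	chr11	68400000	71400000	gain	CCND1,FGF19	0.1304	1.1135	-5.5
22q+	chr22	16000000	51000000	gain		0.1304	0.0863	-3.2
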