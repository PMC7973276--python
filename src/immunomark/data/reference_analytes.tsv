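analyte	kind	median_long	median_short	threshold	p_value	accuracy	ppv	npv	sensitivity	specificity
T_reg cells	cell_percent	5.3	3.2	4.1	0.0829	79	82	75	82	75
CD8+ T cells	cell_percent	2	0.8	1.2	0.1485	74	80	67	73	75
M2 macrophages	cell_percent	0.6	1	0.7	0.0829	63	56	70	62	64
CD4+ T cells	cell_percent	1.4	0.6	0.7	0.1864	63	70	56	64	62
M1 macrophages	cell_percent	0.1	0	0.1	0.2312	63	70	56	64	62
CD14+ monocytes	cell_percent	0.2	0.6	0.4	0.302	63	56	70	62	64
CD19+ B cells	cell_percent	5.9	4	5.3	0.8688	63	70	56	64	62
CD56+ NK cells	cell_percent	1.3	1.4	1.4	0.409	53	44	60	50	54
CTLA4	gene_tpm	3191	1912	2343	0.039	84	83	86	91	75
PD-1	gene_tpm	2612	892	1381	0.0575	74	80	67	73	75
ICOS	gene_tpm	1339	549	896	0.0475	63	70	56	64	62
PD-L1	gene_tpm	1648	900	1388	0.0693	63	70	56	64	62
TIM-3	gene_tpm	5865	6023	5904	0.6797	58	50	64	50	64
OX40	gene_tpm	4580	3727	4010	0.0829	53	60	44	55	50
BTLA	gene_tpm	1385	767	938	0.3218	53	60	44	55	50
CD47	gene_tpm	50296	60332	59375	0.5089	53	44	60	50	55
ARG1	gene_tpm	32	36	35	0.6797	53	44	60	50	55
IDO1	gene_tpm	11162	8732	11037	0.7412	47	56	40	45	50
LAG3	gene_tpm	8041	3618	5416	0.0039	79	82	75	82	75
PDCD1LG2	gene_tpm	2852	1500	1999	0.0986	63	70	56	64	62
LGALS9	gene_tpm	12112	16504	13209	0.3218	63	56	70	62	64
CD96	gene_tpm	6364	2863	4419	0.3218	63	70	56	64	62
CD48	gene_tpm	5288	3924	5009	0.5089	63	70	56	64	62
CD244	gene_tpm	355	412	360	0.8365	53	44	60	50	55
CD40LG	gene_tpm	1078	360	776	0.0693	74	80	67	73	75
CD28	gene_tpm	1483	914	1011	0.1372	74	80	67	73	75
CD27	gene_tpm	5814	2864	3666	0.1864	74	80	67	73	75
TNFRSF18	gene_tpm	4811	2402	3168	0.039	68	73	62	73	62
CD70	gene_tpm	918	593	875	0.1864	63	70	56	64	62
PVRL2	gene_tpm	85599	64526	72381	0.2155	63	70	56	64	62
TNFRSF25	gene_tpm	23986	34522	25030	0.2155	63	56	70	62	64
TNFSF4	gene_tpm	1818	2100	2002	0.2477	63	56	70	62	64
TMIGD2	gene_tpm	331	508	373	0.4828	63	56	70	62	64
CD80	gene_tpm	2318	1994	2218	0.6203	63	70	56	64	62
CD40	gene_tpm	22051	14557	19788	0.7412	63	70	56	64	62
TNFSF18	gene_tpm	75	87	81	1	63	56	70	62	64
HHLA2	gene_tpm	92	265	106	0.3637	53	44	60	50	55
ICOSLG	gene_tpm	421	381	419	0.6203	53	60	44	55	50
TNFSF15	gene_tpm	307	436	410	0.9342	53	44	60	50	55
CD276	gene_tpm	13864	13942	14213	0.8688	47	40	56	50	45
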