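sample_id	group	pfs	os	maint_bev	age_band	ca125_band	debulking
L01	long	90+	90+	no	50-59	0-499	Optimal
L02	long	93+	93+	no	50-59	0-499	Optimal
L03	long	100+	100+	no	50-59	0-499	Optimal
L04	long	84+	84+	no	40-49	0-499	Optimal
L05	long	54	79+	no	90-99	1000-1499	Suboptimal
L06	long	79+	79+	no	40-49	0-499	Optimal
L07	long	62 (51)	77 (66)+	yes	70-79	0-499	Optimal
L08	long	76 (64)+	76 (64)+	yes	50-59	500-999	Optimal
L09	long	71+	71+	no	70-79	0-499	Optimal
L10	long	71+	71+	no	50-59	0-499	Optimal
L11	long	72+	72+	no	60-69	0-499	Optimal
S01	short	2	4	no	60-69	0-499	Suboptimal
S02	short	4	6	no	60-69	N/A	Optimal
S03	short	6	14	no	70-79	0-499	Suboptimal
S04	short	7	28	no	70-79	0-499	Optimal
S05	short	7 (2)	20 (15)	yes	60-69	1500-1999	Suboptimal
S06	short	0 (0)	6 (0)	yes	40-49	0-499	Suboptimal
S07	short	9	18	no	60-69	3000+	Optimal
S08	short	6	24	no	70-79	2500-2999	Optimal
I01	intermediate	16	38	no	70-79	2500-2999	Optimal
I02	intermediate	20 (9)	76 (67)+	yes	60-69	1000-1499	Optimal
I03	intermediate	33 (22)	95 (84)	yes	50-59	0-499	Optimal
I04	intermediate	47 (41)	51 (45)	yes	60-69	0-499	Optimal
I05	intermediate	17	47	no	60-69	0-499	Optimal
I06	intermediate	24	29	no	80-89	0-499	Suboptimal
I07	intermediate	31	56+	no	60-69	0-499	Optimal
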