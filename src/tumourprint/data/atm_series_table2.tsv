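patient_id	sex	age_at_diagnosis	invasive	histology	er	pr	her2	her2_ihc_score	fish_amplified	ki67_pct
P01	F	48	True	ductal	+	+	-	1	unknown	10
P02	F	52	True	ductal	+	+	-	1	unknown	10
P03	F	61	True	ductal	+	+	-	0	unknown	10
P04	F	44	True	ductal	+	+	-	1	unknown	12
P05	F	57	True	lobular	+	+	-	1	unknown	8
P06	F	39	True	lobular	+	+	-	0	unknown	15
P07	F	63	True	ductal	+	+	-	1	unknown	10
P08	F	50	True	ductal	+	+	-	1	unknown	5
P09	F	46	True	ductal	+	-	-	1	unknown	10
P10	F	55	True	ductal	+	-	-	0	unknown	15
P11	F	41	True	ductal	+	+	-	1	unknown	30
P12	F	58	True	ductal	+	+	-	1	unknown	25
P13	F	49	True	ductal	+	+	-	0	unknown	40
P14	F	66	True	ductal	+	+	-	1	unknown	30
P15	F	53	True	other	+	+	-	1	unknown	22
P16	F	45	True	other	+	+	-	1	unknown	35
P17	F	60	True	other	+	+	-	0	unknown	28
P18	F	38	True	ductal	+	+	-	1	unknown	30
P19	F	56	True	ductal	+	+	-	1	unknown	45
P20	F	47	True	ductal	+	-	-	1	unknown	30
P21	F	51	True	ductal	+	-	-	0	unknown	25
P22	F	43	True	ductal	+	-	-	1	unknown	30
P23	F	62	True	ductal	+	-	-	1	unknown	50
P24	F	54	True	ductal	+	+	+	3	unknown	30
P25	F	40	True	ductal	+	+	+	3	unknown	35
P26	F	59	True	ductal	+	+	+	2	yes	25
P27	F	48	True	ductal	+	+	+	2	yes	40
P28	F	36	True	ductal	-	-	-	1	unknown	unknown
P29	F	64	True	ductal	+	+	+	3	unknown	unknown
P30	F	50	True	ductal	+	+	+	2	yes	10
P31	F	57	True	ductal	unknown	-	-	1	unknown	30
P32	F	45	True	ductal	+	unknown	unknown	unknown	unknown	unknown
P33	F	53	True	ductal	+	unknown	unknown	unknown	unknown	unknown
P34	F	49	True	ductal	+	+	unknown	unknown	unknown	unknown
P35	F	61	True	ductal	+	+	unknown	unknown	unknown	unknown
P36	F	42	True	unknown	+	+	unknown	unknown	unknown	unknown
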