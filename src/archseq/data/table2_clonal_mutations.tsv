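gene	hotspot	protein_change	vaf_percent	age	symbol
DNMT3A	DNMT3A R882	p.R882H	4.14	25
DNMT3A	DNMT3A R882	p.R882C	2.33	35
DNMT3A	DNMT3A R882	p.R882H	3.80	42
DNMT3A	DNMT3A R882	p.R882H	4.00	42
DNMT3A	DNMT3A R882	p.R882H	1.25	43
DNMT3A	DNMT3A R882	p.R882H	19.00	48
DNMT3A	DNMT3A R882	p.R882H	1.18	49
DNMT3A	DNMT3A R882	p.R882S	1.74	49
DNMT3A	DNMT3A R882	p.R882H	9.87	50
DNMT3A	DNMT3A R882	p.R882H	0.83	51
DNMT3A	DNMT3A R882	p.R882C	1.10	51
DNMT3A	DNMT3A R882	p.R882C	12.50	52
DNMT3A	DNMT3A R882	p.R882C	1.28	53
DNMT3A	DNMT3A R882	p.R882C	2.47	54
DNMT3A	DNMT3A R882	p.R882H	1.95	55
DNMT3A	DNMT3A R882	p.R882C	30.22	55
DNMT3A	DNMT3A R882	p.R882C	1.22	56
DNMT3A	DNMT3A R882	p.R882H	0.91	58
DNMT3A	DNMT3A R882	p.R882H	4.17	60
DNMT3A	DNMT3A R882	p.R882H	5.90	60
DNMT3A	DNMT3A R882	p.R882H	9.60	60
DNMT3A	DNMT3A R882	p.R882H	2.73	60
DNMT3A	DNMT3A R882	p.R882C	9.33	60
DNMT3A	DNMT3A R882	p.R882H	7.03	61
DNMT3A	DNMT3A R882	p.R882C	1.21	61
DNMT3A	DNMT3A R882	p.R882H	0.86	63
DNMT3A	DNMT3A R882	p.R882H	2.54	64
DNMT3A	DNMT3A R882	p.R882H	3.19	67
DNMT3A	DNMT3A R882	p.R882H	2.74	70
DNMT3A	DNMT3A R882	p.R882H	4.27	74
DNMT3A	DNMT3A R882	p.R882H	0.85	74
DNMT3A	DNMT3A R882	p.R882H	0.85	75
DNMT3A	DNMT3A R882	p.R882C	1.12	77
DNMT3A	DNMT3A R882	p.R882C	1.15	78
DNMT3A	DNMT3A R882	p.R882H	1.26	79
DNMT3A	DNMT3A R882	p.R882H	16.66	80
DNMT3A	DNMT3A R882	p.R882C	4.28	80
DNMT3A	DNMT3A R882	p.R882C	3.66	80
DNMT3A	DNMT3A R882	p.R882H	32.02	81
DNMT3A	DNMT3A R882	p.R882H	1.14	81
DNMT3A	DNMT3A R882	p.R882H	3.06	81
DNMT3A	DNMT3A R882	p.R882H	2.17	81
DNMT3A	DNMT3A R882	p.R882H	1.13	82
DNMT3A	DNMT3A R882	p.R882H	1.46	82
DNMT3A	DNMT3A R882	p.R882C	2.62	82
DNMT3A	DNMT3A R882	p.R882C	6.15	89
DNMT3A	DNMT3A R882	p.R882C	2.00	94
JAK2	JAK2 V617	p.V617F	1.56	34
JAK2	JAK2 V617	p.V617F	4.91	42
JAK2	JAK2 V617	p.V617F	7.72	45
JAK2	JAK2 V617	p.V617F	0.85	62
JAK2	JAK2 V617	p.V617F	25.44	64
JAK2	JAK2 V617	p.V617F	7.41	65
JAK2	JAK2 V617	p.V617F	1.03	67
JAK2	JAK2 V617	p.V617F	0.88	71
JAK2	JAK2 V617	p.V617F	3.75	71
JAK2	JAK2 V617	p.V617F	1.16	75
JAK2	JAK2 V617	p.V617F	2.30	77
JAK2	JAK2 V617	p.V617F	1.92	78
JAK2	JAK2 V617	p.V617F	2.26	80	*
JAK2	JAK2 V617	p.V617F	4.25	80
JAK2	JAK2 V617	p.V617F	1.92	80
JAK2	JAK2 V617	p.V617F	3.71	80
JAK2	JAK2 V617	p.V617F	15.48	81
JAK2	JAK2 V617	p.V617F	1.21	82
JAK2	JAK2 V617	p.V617F	1.62	85
JAK2	JAK2 V617	p.V617F	0.83	85
JAK2	JAK2 V617	p.V617F	1.98	86
JAK2	JAK2 V617	p.V617F	25.94	88
JAK2	JAK2 V617	p.V617F	10.88	88	**
JAK2	JAK2 V617	p.V617F	2.94	90
JAK2	JAK2 V617	p.V617F	1.23	90
KRAS	KRAS G12	p.G12R	0.94	55
KRAS	KRAS G12	p.G12S	2.78	78
NRAS	NRAS G12	p.G12S	1.50	61
NRAS	NRAS G12	p.G12D	0.96	62
IDH1	IDH1 R132	p.R132H	42.13	84
IDH1	IDH1 R132	p.R132C	0.92	92
IDH2	IDH2 R140	p.R140Q	6.67	76
SRSF2	SRSF2 P95	p.P95R	4.46	70
SRSF2	SRSF2 P95	p.P95L	3.35	72
SRSF2	SRSF2 P95	p.P95H	0.86	73
SRSF2	SRSF2 P95	p.P95H	0.84	77
SRSF2	SRSF2 P95	p.P95L	0.97	79	+
SRSF2	SRSF2 P95	p.P95L	0.85	80	++
SRSF2	SRSF2 P95	p.P95H	6.67	80	++
SRSF2	SRSF2 P95	p.P95L	0.96	81
SRSF2	SRSF2 P95	p.P95H	6.40	82
SRSF2	SRSF2 P95	p.P95L	2.74	85
SRSF2	SRSF2 P95	p.P95R	7.52	87
SRSF2	SRSF2 P95	p.P95L	5.84	88	**
SRSF2	SRSF2 P95	p.P95H	10.48	88	**
SRSF2	SRSF2 P95	p.P95R	2.71	88
SRSF2	SRSF2 P95	p.P95R	17.05	90	#
SF3B1	SF3B1 K700	p.K700E	1.04	76
SF3B1	SF3B1 K700	p.K700E	6.63	81
SF3B1	SF3B1 K700	p.K700E	0.79	82
SF3B1	SF3B1 K700	p.K700E	12.59	83
SF3B1	SF3B1 K700	p.K700E	8.77	83	##
SF3B1	SF3B1 K700	p.K700E	1.02	84
SF3B1	SF3B1 K700	p.K700E	0.85	90	#
SF3B1	SF3B1 K700	p.K700E	1.37	90
SF3B1	SF3B1 K666	p.K666N	1.33	70
SF3B1	SF3B1 K666	p.K666N	5.01	79
SF3B1	SF3B1 K666	p.K666N	13.36	79	+
SF3B1	SF3B1 K666	p.K666N	15.43	80	*
SF3B1	SF3B1 K666	p.K666N	4.60	81
SF3B1	SF3B1 K666	p.K666E	1.09	83	##
SF3B1	SF3B1 K666	p.K666N	35.11	86
SF3B1	SF3B1 K666	p.K666N	19.70	86
SF3B1	SF3B1 K666	p.K666N	16.55	86
SF3B1	SF3B1 K666	p.K666E	3.34	95
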