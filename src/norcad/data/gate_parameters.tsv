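name	repressor_family	y_min	y_max	K	n	alpha	beta	tau_on	tau_off
F1-AmeR_2	AmeR	0.29	4.6	0.12	1.5	0.09	1.00	8.00	2.30
F2-AmeR_2	AmeR	0.21	3.7	0.04	1.3	0.10	1.00	8.00	2.50
N1-LmrA_2	LmrA	0.077	1.3	0.09	1.8	0.28	1.00	1.00	1.30
A1-AmtR_2	AmtR	0.035	3.1	0.05	1.7	0.27	1.00	0.90	2.50
H1-HlyIIR_2	HlyIIR	0.004	2.1	0.13	2.6	0.15	1.00	0.45	4.00
P1-PhlF	PhlF	0.004	6.9	0.04	3.8	0.22	0.06	0.30	4.00
P2-PhlF	PhlF	0.007	7.5	0.21	4.5	0.15	0.12	0.20	4.00
P3-PhlF	PhlF	0.004	7.1	0.12	3.3	0.24	0.06	0.15	5.00
S1-SrpR	SrpR	0.001	1.4	0.02	3.1	0.50	0.05	5.00	7.00
S2-SrpR	SrpR	0.003	3.2	0.06	2.7	0.35	0.09	0.50	7.00
S3-SrpR	SrpR	0.004	3.1	0.09	2.7	0.33	0.10	0.70	6.00
S4-SrpR	SrpR	0.004	3.2	0.11	2.7	0.38	0.09	1.80	8.00
E1-BetI_2	BetI	0.041	2.8	0.28	2.9	0.64	0.46	0.40	1.50
B1-BM3R1	BM3R1	0.004	0.6	0.06	2.9	0.64	0.05	0.90	1.10
B2-BM3R1	BM3R1	0.006	0.5	0.57	3.8	0.71	0.05	0.90	1.10
B3-BM3R1	BM3R1	0.005	0.6	0.21	3.1	0.74	0.05	0.50	2.00
C1-CymR	CymR	0.010	3.0	0.10	3.7	0.10	0.07	0.50	2.50
V1-VanR	VanR	0.043	6.2	0.05	2.9	0.12	0.32	0.40	11.0
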