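gene	group	rat_id	m0	sem
Ascl3	aggressive	A1	0.16	0.02
Ascl3	aggressive	A2	0.88	0.30
Ascl3	aggressive	A3	0.82	0.08
Ascl3	aggressive	A4	0.09	0.04
Ascl3	aggressive	A5	0.18	0.03
Ascl3	aggressive	A6	0.07	0.07
Ascl3	aggressive	A7	0.27	0.11
Ascl3	aggressive	A8	0.32	0.05
Ascl3	tame	T1	4.85	4.38
Ascl3	tame	T2	3.40	1.69
Ascl3	tame	T3	1.75	0.24
Ascl3	tame	T4	2.21	0.12
Ascl3	tame	T5	2.92	0.05
Ascl3	tame	T6	4.48	0.17
Ascl3	tame	T7	3.83	0.33
Ascl3	tame	T8	2.64	0.15
Defb17	aggressive	A1	0.005	0.005
Defb17	aggressive	A2	0.01	0.005
Defb17	aggressive	A3	0.005	0.005
Defb17	aggressive	A4	0.005	0.005
Defb17	aggressive	A5	0.005	0.005
Defb17	aggressive	A6	ND	ND
Defb17	aggressive	A7	0.005	0.005
Defb17	aggressive	A8	0.005	0.005
Defb17	tame	T1	1.72	0.04
Defb17	tame	T2	3.22	0.42
Defb17	tame	T3	2.52	0.14
Defb17	tame	T4	1.82	0.55
Defb17	tame	T5	2.45	0.10
Defb17	tame	T6	4.43	0.26
Defb17	tame	T7	1.99	0.89
Defb17	tame	T8	2.34	0.27
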