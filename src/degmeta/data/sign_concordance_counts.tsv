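gene	n_pc1	n_pc2	p_printed	p_adj_printed
Alb	1	1	0.75	1.00
Aqp1	6	6	0.61	1.00
Ascl3	1	1	0.75	1.00
Bag3	2	2	0.69	1.00
Baiap2l1	1	0	0.50	1.00
Bdh1	2	0	0.25	1.00
Cckbr	1	0	0.50	1.00
Cspg4b	0	0	ND	ND
Defb17	2	3	0.50	1.00
Enpp2	3	8	0.11	1.00
Frem1	1	1	0.75	1.00
Gpd1	4	1	0.19	1.00
Hbb-b1	24	3	1e-4	1e-3
Hnf4a	0	0	ND	ND
Htr2c	3	3	0.65	1.00
Krt2	22	13	0.09	1.00
Lilrb3l	10	1	1e-2	0.24
Lypd1	11	7	0.24	1.00
Morn1	0	4	0.06	1.00
Myom2	2	1	0.50	1.00
Pcdhb9	10	0	1e-3	0.05
Pcdhga1	1	1	0.75	1.00
Pdyn	0	0	ND	ND
Pla2g2d	19	12	0.14	1.00
Pla2g5	19	12	0.14	1.00
Plod1	3	1	0.31	1.00
Ppp1r3b	2	3	0.50	1.00
Prlr	0	1	0.50	1.00
Pygl	0	1	0.50	1.00
Rbm3	15	12	0.35	1.00
Retsat	5	2	0.23	1.00
Slc16a12	7	6	0.50	1.00
Slc4a5	7	5	0.83	1.00
Smoc2	3	1	0.31	1.00
Spint1	1	1	0.75	1.00
Sulf1	0	0	ND	ND
Sync	0	0	ND	ND
Tc2n	2	0	0.25	1.00
Tecta	0	1	0.50	1.00
Tmem60	0	0	ND	ND
Txnrd2	2	0	0.25	1.00
Ucp2	1	1	0.75	1.00
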