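study_id	species	tissue	contrast	gene	log2	p	p_adj
this_study	rat	hippocampus	tame_vs_aggressive	Alb	3.21	<1e-11	<1e-7
this_study	rat	hippocampus	tame_vs_aggressive	Aqp1	5.91	<1e-6	<1e-2
this_study	rat	hippocampus	tame_vs_aggressive	Ascl3	2.38	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Bag3	-0.92	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Baiap2l1	3.67	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Bdh1	0.40	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Cckbr	1.24	<1e-8	<1e-4
this_study	rat	hippocampus	tame_vs_aggressive	Cspg4b	3.47	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Defb17	5.94	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Enpp2	2.41	<1e-3	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Frem1	3.16	<1e-3	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Gpd1	-1.34	<1e-6	<1e-3
this_study	rat	hippocampus	tame_vs_aggressive	Hbb-b1	-6.19	<1e-7	<1e-4
this_study	rat	hippocampus	tame_vs_aggressive	Hnf4a	6.51	<1e-3	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Htr2c	2.03	<1e-3	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Krt2	-1.43	<1e-6	<1e-3
this_study	rat	hippocampus	tame_vs_aggressive	Lilrb3l	7.45	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Lypd1	-0.89	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Morn1	1.42	<1e-11	<1e-7
this_study	rat	hippocampus	tame_vs_aggressive	Myom2	-1.24	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Pcdhb9	-1.03	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Pcdhga1	2.45	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Pdyn	-0.89	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Pla2g2d	2.84	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Pla2g5	3.85	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Plod1	-0.67	<1e-3	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Ppp1r3b	2.45	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Prlr	6.43	<1e-5	<1e-2
this_study	rat	hippocampus	tame_vs_aggressive	Pygl	-1.21	<1e-5	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Rbm3	0.89	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Retsat	-0.98	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Slc16a12	3.08	<1e-3	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Slc4a5	6.27	<1e-6	<1e-3
this_study	rat	hippocampus	tame_vs_aggressive	Smoc2	-2.09	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Spint1	-1.39	<1e-7	<1e-4
this_study	rat	hippocampus	tame_vs_aggressive	Sulf1	3.72	<1e-6	<1e-2
this_study	rat	hippocampus	tame_vs_aggressive	Sync	1.17	<1e-3	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Tc2n	3.47	<1e-5	<1e-2
this_study	rat	hippocampus	tame_vs_aggressive	Tecta	1.38	<1e-8	<1e-5
this_study	rat	hippocampus	tame_vs_aggressive	Tmem60	0.79	<1e-4	<0.05
this_study	rat	hippocampus	tame_vs_aggressive	Txnrd2	-0.71	<1e-5	<1e-2
this_study	rat	hippocampus	tame_vs_aggressive	Ucp2	0.73	<1e-4	<0.05
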