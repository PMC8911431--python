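study_id	species	tissue	contrast	gene	log2	p	p_adj
isiah_wag	rat	brain_stem	hypertensive_vs_normotensive	Hbb-b1	1.42	1e-2	1e-2
isiah_wag	rat	hypothalamus	hypertensive_vs_normotensive	Hbb-b1	2.02	1e-2	1e-2
isiah_wag	rat	renal_medulla	hypertensive_vs_normotensive	Hbb-b1	1.18	1e-2	1e-2
isiah_wag	rat	adrenal_gland	hypertensive_vs_normotensive	Hbb-b1	1.32	1e-2	1e-2
isiah_wag	rat	adrenal_gland	hypertensive_vs_normotensive	Hba2	0.69	1e-2	1e-2
isiah_wag	rat	adrenal_gland	hypertensive_vs_normotensive	Hbb	2.02	1e-2	1e-2
isiah_wag	rat	adrenal_gland	hypertensive_vs_normotensive	Hbb-m	3.78	1e-2	1e-2
isiah_wag	rat	brain_stem	hypertensive_vs_normotensive	Hba2	0.58	0.05	0.05
isiah_wag	rat	brain_stem	hypertensive_vs_normotensive	Hbb	1.88	1e-2	1e-2
isiah_wag	rat	brain_stem	hypertensive_vs_normotensive	Hbb-m	3.65	1e-2	1e-2
isiah_wag	rat	hypothalamus	hypertensive_vs_normotensive	Hba1	1.14	1e-2	1e-2
isiah_wag	rat	hypothalamus	hypertensive_vs_normotensive	Hba2	1.32	1e-2	1e-2
isiah_wag	rat	hypothalamus	hypertensive_vs_normotensive	Hbb	3.23	1e-2	1e-2
isiah_wag	rat	hypothalamus	hypertensive_vs_normotensive	Hbb-m	1.09	1e-2	1e-2
isiah_wag	rat	renal_medulla	hypertensive_vs_normotensive	Hbb	-0.68	1e-2	1e-2
isiah_wag	rat	renal_medulla	hypertensive_vs_normotensive	Hbb-m	2.72	1e-2	1e-2
isiah_wag	rat	renal_medulla	hypertensive_vs_normotensive	Hbb-s	2.38	1e-2	1e-2
preeclampsia_placenta	human	placenta	hypertensive_vs_normotensive	HBD	-0.63	1e-3	1e-3
pulm_fib_lung	human	lungs	hypertensive_vs_normotensive	HBD	-2.83	1e-3	1e-3
pulm_ht_lung	human	lungs	hypertensive_vs_normotensive	HBA1	2.08	1e-9	1e-9
pulm_ht_lung	human	lungs	hypertensive_vs_normotensive	HBB	2.46	1e-10	1e-10
coronary_blood	human	peripheral_blood	hypertensive_vs_normotensive	HBBP1	1.03	0.05	0.05
coronary_blood	human	peripheral_blood	hypertensive_vs_normotensive	HBE1	1.42	0.05	0.05
coronary_blood	human	peripheral_blood	hypertensive_vs_normotensive	HBG2	4.49	0.05	0.05
coronary_blood	human	peripheral_blood	hypertensive_vs_normotensive	HBM	5.33	0.05	0.05
coronary_blood	human	peripheral_blood	hypertensive_vs_normotensive	HBQ1	3.10	0.05	0.05
afib_auricle	human	auricle_tissue	hypertensive_vs_normotensive	HBA2	2.37	1e-2	1e-2
isiah_wag	rat	brain_stem	hypertensive_vs_normotensive	Pcdhb7	1.60	1e-2	1e-2
bph_bpn_kidney	mouse	kidneys	hypertensive_vs_normotensive	Pcdhb16	1.22	1e-3	1e-3
pulm_fib_lung	human	lungs	hypertensive_vs_normotensive	PCDHB10	1.89	1e-2	1e-2
pulm_fib_lung	human	lungs	hypertensive_vs_normotensive	PCDHB15	1.47	1e-4	1e-4
pulm_fib_lung	human	lungs	hypertensive_vs_normotensive	PCDHB16	1.38	1e-4	1e-4
pulm_fib_lung	human	lungs	hypertensive_vs_normotensive	PCDHB17P	1.21	1e-2	1e-2
pulm_fib_lung	human	lungs	hypertensive_vs_normotensive	PCDHB4	2.93	1e-4	1e-4
pulm_fib_lung	human	lungs	hypertensive_vs_normotensive	PCDHB6	1.35	1e-2	1e-2
coronary_blood	human	peripheral_blood	hypertensive_vs_normotensive	PCDHB11	1.12	0.05	0.05
coronary_blood	human	peripheral_blood	hypertensive_vs_normotensive	PCDHB13	1.04	0.05	0.05
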