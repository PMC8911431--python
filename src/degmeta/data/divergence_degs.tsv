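study_id	species	tissue	contrast	gene	log2	p	p_adj	family
this_study	rat	hippocampus	domestic_vs_wild	Hbb-b1	-6.19	0.05	0.05	hemoglobin
tame_hypothalamus	rat	hypothalamus	domestic_vs_wild	Hbb-b1	-3.97	0.05	0.05	hemoglobin
dog_wolf_blood	dog	blood	domestic_vs_wild	Hbbl	-5.92	0.05	0.05	hemoglobin
dog_wolf_blood	dog	blood	domestic_vs_wild	Hba1	-4.06	0.05	0.05	hemoglobin
chicken_pituitary	chicken	pituitary	domestic_vs_wild	Hbad	-1.07	0.05	0.05	hemoglobin
dog_wolf_blood	dog	blood	domestic_vs_wild	Hbm	-6.46	0.05	0.05	hemoglobin
dog_wolf_blood	dog	blood	domestic_vs_wild	Hbz1	-7.10	0.05	0.05	hemoglobin
this_study	rat	hippocampus	domestic_vs_wild	Pcdhb9	-1.03	0.05	0.05	beta-protocadherin
tame_hypothalamus	rat	hypothalamus	domestic_vs_wild	Pcdhb9	-1.01	0.05	0.05	beta-protocadherin
rabbit_cortex	rabbit	parietal_temporal_cortex	domestic_vs_wild	Pcdhb15	-1.04	0.05	0.05	beta-protocadherin
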