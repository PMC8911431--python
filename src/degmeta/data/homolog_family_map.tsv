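seed_gene	partner_gene	partner_species	family
Hbb-b1	Hbb-b1	rat	hemoglobin
Hbb-b1	Hba1	rat	hemoglobin
Hbb-b1	Hba2	rat	hemoglobin
Hbb-b1	Hbb	rat	hemoglobin
Hbb-b1	Hbb-m	rat	hemoglobin
Hbb-b1	Hbb-s	rat	hemoglobin
Hbb-b1	HBA1	human	hemoglobin
Hbb-b1	HBA2	human	hemoglobin
Hbb-b1	HBB	human	hemoglobin
Hbb-b1	HBBP1	human	hemoglobin
Hbb-b1	HBD	human	hemoglobin
Hbb-b1	HBE1	human	hemoglobin
Hbb-b1	HBG2	human	hemoglobin
Hbb-b1	HBM	human	hemoglobin
Hbb-b1	HBQ1	human	hemoglobin
Pcdhb9	Pcdhb7	rat	beta-protocadherin
Pcdhb9	Pcdhb16	mouse	beta-protocadherin
Pcdhb9	PCDHB4	human	beta-protocadherin
Pcdhb9	PCDHB6	human	beta-protocadherin
Pcdhb9	PCDHB10	human	beta-protocadherin
Pcdhb9	PCDHB11	human	beta-protocadherin
Pcdhb9	PCDHB13	human	beta-protocadherin
Pcdhb9	PCDHB15	human	beta-protocadherin
Pcdhb9	PCDHB16	human	beta-protocadherin
Pcdhb9	PCDHB17P	human	beta-protocadherin
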