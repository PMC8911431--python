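gene	downregulation_direction	rationale
HBB	normotensive	low blood viscosity
HBD	normotensive	low blood viscosity
PCDHB9	normotensive	wide vascular inner diameter
Hbb-b1	normotensive	hemoglobin family: low blood viscosity
Hbbl	normotensive	hemoglobin family: low blood viscosity
Hba1	normotensive	hemoglobin family: low blood viscosity
Hbad	normotensive	hemoglobin family: low blood viscosity
Hbm	normotensive	hemoglobin family: low blood viscosity
Hbz1	normotensive	hemoglobin family: low blood viscosity
Pcdhb9	normotensive	beta-protocadherin family: wide vascular inner diameter
Pcdhb15	normotensive	beta-protocadherin family: wide vascular inner diameter
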