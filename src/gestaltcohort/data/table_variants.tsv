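# Cohort variant table (transcript NM_004204.3); criteria are +-separated ACMG codes.
# classification = classification printed in the source cohort table.
patient_id	cdna	protein	zygosity	criteria	classification
P1	c.1199_1201del	p.(Tyr400del)	het	PP5+PM4+PM2	Pathogenic
P1	c.1092dupC	p.(Phe365LeufsTer78)	het	PVS1+PM2	Likely pathogenic
P2	c.1199_1201del	p.(Tyr400del)	het	PP5+PM4+PM2	Pathogenic
P2	c.1370T>G	p.(Leu457Arg)	het	PM2+PP3+PS3	Likely pathogenic
P3	c.1673del	p.(Gly558AlafsTer65)	hom	PM2	VUS
P4	c.1199_1201del	p.(Tyr400del)	het	PP5+PM4+PM2	Pathogenic
P4	c.942+1G>A	IVS4+1G>A	het	PVS1+PP5+PM2	Pathogenic
P5	c.1640_1641del	p.(Pro547GlnfsTer235)	het	PVS1+PM2	Likely pathogenic
P5	c.1199_1201del	p.(Tyr400del)	het	PP5+PM4+PM2	Pathogenic
P6	c.1640_1641del	p.(Pro547GlnfsTer235)	het	PVS1+PM2	Likely pathogenic
P6	c.1199_1201del	p.(Tyr400del)	het	PP5+PM4+PM2	Pathogenic
P7	c.1130_1168del	p.(Ala377_Ser389del)	het	PM4+PM2	VUS
P7	c.1345G>C	p.(Gly449Arg)	het	PM3+PM2+PP3	Likely pathogenic
P8	c.49G>A	p.(Gly17Arg)	het	PM2+PP3	VUS
P8	c.942+1G>A	IVS4+1G>A	het	PVS1+PP5+PM2	Pathogenic
P9	c.1732del	p.(Asp578ThrfsTer45)	hom	PVS1+PM2	Likely pathogenic
P10	c.690-2A>G	p.?	hom	PM3+PVS1+PM2	Pathogenic
P11	c.619C>T	p.(Arg207Ter)	hom	PM3+PVS1+PM2	Pathogenic
P12	c.968_969del	p.(Leu323ProfsTer119)	het	PM3+PVS1+PM2	Pathogenic
P12	c.1199_1201del	p.(Tyr400del)	het	PP5+PM4+PM2	Pathogenic
P13	c.1631dupA	p.(Tyr544fsTer79)	hom	PVS1+PM2	Likely pathogenic
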