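step_id	substrates	products	ec_list	reversible	tags
prpp_1	R1P	R5P	5.4.2.2,5.4.2.7	1	de_novo
prpp_2	R5P	PRPP	2.7.6.1	0	de_novo
pur_1	PRPP	PRA	2.4.2.14	0	de_novo
pur_2	PRA	GAR	6.3.4.13	0	de_novo
pur_3	GAR	FGAR	2.1.2.2	0	de_novo
pur_4	FGAR	FGAM	6.3.5.3	0	de_novo
pur_5	FGAM	AIR	6.3.3.1	0	de_novo
cair_direct	AIR	CAIR	4.1.1.21	0	de_novo,co2_dependent
cair_1	AIR	NCAIR	6.3.4.18	0	de_novo,hco3_dependent
cair_2	NCAIR	CAIR	5.4.99.18	0	de_novo
pur_6	CAIR	SAICAR	6.3.2.6	0	de_novo
pur_7	SAICAR	AICAR	4.3.2.2	0	de_novo
purh_1	AICAR	FAICAR	2.1.2.3	0	de_novo,folate_dependent
purh_2	FAICAR	IMP	3.5.4.10	0	de_novo,folate_dependent
purp	AICAR	FAICAR	2.1.2.3	0	de_novo,archaea_specific
puro	FAICAR	IMP	3.5.4.10	0	de_novo,archaea_specific
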