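step_id	substrates	products	ec_list	reversible	tags
pyr_1	Gln,HCO3	CarbamoylP	6.3.5.5,6.3.4.16	0	de_novo
pyr_2	CarbamoylP,Asp	CarbamoylAsp	2.1.3.2	0	de_novo
pyr_3	CarbamoylAsp	Dihydroorotate	3.5.2.3	0	de_novo
pyr_4	Dihydroorotate	Orotate	1.3.1.14,1.3.5.2,1.3.98.1	0	de_novo
pyr_5	Orotate,PRPP	OMP	2.4.2.10	0	de_novo
pyr_6	OMP	UMP	4.1.1.23	0	de_novo
pyr_7	UMP	UDP	2.7.4.22,2.7.4.14	0	de_novo
pyr_8	UDP	UTP	2.7.4.6	0	de_novo
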