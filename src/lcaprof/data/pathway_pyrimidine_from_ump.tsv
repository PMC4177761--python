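step_id	substrates	products	ec_list	reversible	tags
ctps	UTP	CTP	6.3.4.2	0	de_novo
ndk_c	CDP	CTP	2.7.4.6	1	de_novo
rnr_c	CDP	dCDP	1.17.4.1	0	de_novo
ndk_dc	dCDP	dCTP	2.7.4.6	0	de_novo
dctp_deam	dCTP	dUTP	3.5.4.13	0	de_novo
dutpase	dUTP	dUMP	3.6.1.19	0	de_novo
dcmp_deam	dCMP	dUMP	3.5.4.12	0	de_novo
thy_syn	dUMP	dTMP	2.1.1.45,2.1.1.148	0	de_novo,folate_dependent
tmpk	dTMP	dTDP	2.7.4.9	0	de_novo
ndk_dt	dTDP	dTTP	2.7.4.6	0	de_novo
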