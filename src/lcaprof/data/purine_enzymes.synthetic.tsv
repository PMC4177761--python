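ec_number	name	pathway
5.4.2.2	phosphoglucomutase	purine
5.4.2.7	phosphopentomutase	purine
2.7.6.1	ribose-phosphate diphosphokinase	purine
2.4.2.14	amidophosphoribosyltransferase	purine
6.3.4.13	phosphoribosylamine--glycine ligase	purine
2.1.2.2	phosphoribosylglycinamide formyltransferase	purine
6.3.5.3	phosphoribosylformylglycinamidine synthase	purine
6.3.3.1	phosphoribosylformylglycinamidine cyclo-ligase	purine
4.1.1.21	phosphoribosylaminoimidazole carboxylase	purine
6.3.4.18	5-(carboxyamino)imidazole ribonucleotide synthase	purine
5.4.99.18	5-(carboxyamino)imidazole ribonucleotide mutase	purine
6.3.2.6	phosphoribosylaminoimidazolesuccinocarboxamide synthase	purine
4.3.2.2	adenylosuccinate lyase	purine
2.1.2.3	phosphoribosylaminoimidazolecarboxamide formyltransferase	purine
3.5.4.10	IMP cyclohydrolase	purine
6.3.4.4	adenylosuccinate synthase	purine
2.7.4.3	adenylate kinase	purine
2.7.4.6	nucleoside-diphosphate kinase	purine
2.7.1.40	pyruvate kinase	purine
1.17.4.1	ribonucleoside-diphosphate reductase	purine
1.17.4.2	ribonucleoside-triphosphate reductase	purine
2.4.2.7	adenine phosphoribosyltransferase	purine
2.4.2.8	hypoxanthine-guanine phosphoribosyltransferase	purine
1.1.1.205	IMP dehydrogenase	purine
6.3.5.2	GMP synthase (glutamine-hydrolysing)	purine
6.3.4.1	GMP synthase (ammonia)	purine
2.7.4.8	guanylate kinase	purine
1.7.1.7	GMP reductase	purine
3.5.4.4	adenosine deaminase	purine
3.5.4.2	adenine deaminase	purine
3.5.4.3	guanine deaminase	purine
3.5.4.6	AMP deaminase	purine
3.5.4.15	guanosine deaminase	purine
3.5.4.17	adenosine-phosphate deaminase	purine
2.4.2.1	purine-nucleoside phosphorylase	purine
2.4.2.15	guanosine phosphorylase	purine
2.4.2.22	xanthine phosphoribosyltransferase	purine
2.4.2.28	S-methyl-5'-thioadenosine phosphorylase	purine
3.2.2.1	purine nucleosidase	purine
3.2.2.2	inosine nucleosidase	purine
3.2.2.4	AMP nucleosidase	purine
3.2.2.9	adenosylhomocysteine nucleosidase	purine
3.2.2.12	inosinate nucleosidase	purine
2.7.1.20	adenosine kinase	purine
2.7.1.73	inosine kinase	purine
2.7.1.76	deoxyadenosine kinase	purine
2.7.1.113	deoxyguanosine kinase	purine
2.7.4.11	(deoxy)adenylate kinase	purine
3.1.3.5	5'-nucleotidase	purine
3.6.1.3	adenosinetriphosphatase	purine
3.6.1.5	apyrase	purine
3.6.1.6	nucleoside-diphosphatase	purine
3.6.1.8	ATP diphosphatase	purine
3.6.1.13	ADP-ribose diphosphatase	purine
3.6.1.17	bis(5'-nucleosyl)-tetraphosphatase	purine
3.6.1.29	bis(5'-adenosyl)-triphosphatase	purine
3.6.1.41	bis(5'-adenosyl)-hexaphosphatase	purine
1.17.1.4	xanthine dehydrogenase	purine
1.17.3.2	xanthine oxidase	purine
1.7.3.3	factor-independent urate hydroxylase	purine
3.5.2.5	allantoinase	purine
3.5.3.4	allantoicase	purine
3.5.3.9	allantoate deiminase	purine
3.5.1.5	urease	purine
4.3.2.3	ureidoglycolate lyase	purine
1.1.1.154	ureidoglycolate dehydrogenase	purine
3.1.4.17	3',5'-cyclic-nucleotide phosphodiesterase	purine
3.1.4.35	3',5'-cyclic-GMP phosphodiesterase	purine
4.6.1.1	adenylate cyclase	purine
4.6.1.2	guanylate cyclase	purine
2.7.4.10	nucleoside-triphosphate--adenylate kinase	purine
2.7.4.4	nucleoside-phosphate kinase	purine
3.5.4.16	GTP cyclohydrolase I	purine
3.5.4.25	GTP cyclohydrolase II	purine
2.7.4.23	ribose 1,5-bisphosphate phosphokinase	purine
2.7.7.53	ATP adenylyltransferase	purine
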