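ec_number	name	pathway
6.3.5.5	carbamoyl-phosphate synthase (glutamine-hydrolysing)	pyrimidine
6.3.4.16	carbamoyl-phosphate synthase (ammonia)	pyrimidine
2.1.3.2	aspartate carbamoyltransferase	pyrimidine
3.5.2.3	dihydroorotase	pyrimidine
1.3.1.14	dihydroorotate dehydrogenase (NAD+)	pyrimidine
1.3.5.2	dihydroorotate dehydrogenase (quinone)	pyrimidine
1.3.98.1	dihydroorotate dehydrogenase (fumarate)	pyrimidine
2.4.2.10	orotate phosphoribosyltransferase	pyrimidine
4.1.1.23	orotidine-5'-phosphate decarboxylase	pyrimidine
2.7.4.14	UMP/CMP kinase	pyrimidine
2.7.4.22	UMP kinase	pyrimidine
2.7.4.25	(d)CMP kinase	pyrimidine
6.3.4.2	CTP synthase	pyrimidine
1.8.1.9	thioredoxin-disulfide reductase	pyrimidine
3.6.1.19	nucleoside-triphosphate diphosphatase	pyrimidine
3.6.1.23	dUTP diphosphatase	pyrimidine
3.6.1.12	dCTP diphosphatase	pyrimidine
3.5.4.12	dCMP deaminase	pyrimidine
3.5.4.13	dCTP deaminase	pyrimidine
3.5.4.30	dCTP deaminase (dUMP-forming)	pyrimidine
2.1.1.45	thymidylate synthase	pyrimidine
2.1.1.148	thymidylate synthase (FAD)	pyrimidine
2.7.4.9	dTMP kinase	pyrimidine
2.7.1.21	thymidine kinase	pyrimidine
2.4.2.4	thymidine phosphorylase	pyrimidine
2.7.1.48	uridine kinase	pyrimidine
2.4.2.3	uridine phosphorylase	pyrimidine
2.4.2.9	uracil phosphoribosyltransferase	pyrimidine
2.4.2.2	pyrimidine-nucleoside phosphorylase	pyrimidine
3.5.4.5	cytidine deaminase	pyrimidine
3.5.4.1	cytosine deaminase	pyrimidine
2.7.1.74	deoxycytidine kinase	pyrimidine
2.7.1.145	deoxyribonucleoside kinase	pyrimidine
2.4.2.6	nucleoside deoxyribosyltransferase	pyrimidine
3.2.2.3	uridine nucleosidase	pyrimidine
3.2.2.8	ribosylpyrimidine nucleosidase	pyrimidine
3.2.2.10	pyrimidine-5'-nucleotide nucleosidase	pyrimidine
3.5.2.2	dihydropyrimidinase	pyrimidine
3.5.1.6	beta-ureidopropionase	pyrimidine
1.3.1.1	dihydrouracil dehydrogenase (NAD+)	pyrimidine
1.3.1.2	dihydropyrimidine dehydrogenase (NADP+)	pyrimidine
1.14.11.6	thymine dioxygenase	pyrimidine
3.1.3.35	thymidylate 5'-phosphatase	pyrimidine
3.1.3.89	5'-deoxynucleotidase	pyrimidine
2.7.4.6	nucleoside-diphosphate kinase	pyrimidine
1.17.4.1	ribonucleoside-diphosphate reductase	pyrimidine
1.17.4.2	ribonucleoside-triphosphate reductase	pyrimidine
3.1.3.5	5'-nucleotidase	pyrimidine
2.7.1.40	pyruvate kinase	pyrimidine
2.7.6.1	ribose-phosphate diphosphokinase	pyrimidine
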