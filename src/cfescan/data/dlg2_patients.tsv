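patient_id	chrom	start	end	size_mb	state	gender	other_rare_cnvs	inheritance	phenotype	deleted_features_printed
317136	chr11	84245639	84772741	0.52	deletion	male	0	inherited from an unaffected mother	C,B	Exons 7-8; HPin7
317185	chr11	84334015	84797219	0.46	deletion	male	0	inherited from an unaffected mother	C,B	Exon 7; HPin7
248668	chr11	84548697	84628963	0.08	deletion	male	32	unknown	C	Intron 7
256592	chr11	84456097	84607440	0.15	deletion	male	1	unknown	C,B	Intron 7
263216	chr11	84003279	84276072	0.27	deletion	male	0	inherited from a parent with same phenotype	unknown	Exons 8-9; HPin8
270892	chr11	84108622	84334253	0.23	deletion	male	0	inherited from normal parent	C,B	Exon 8; HPin8
272251	chr11	83805117	84215024	0.41	deletion	female	3	inherited from an unaffected mother	C,B,P	Exons 9-13; HPin8
273969	chr11	83996254	84214903	0.22	deletion	male	0	unknown	unknown	Exon 9; HPin8
278011	chr11	84367238	84721340	0.35	deletion	male	1	de novo constitutive	C	Exon 7; HPin7
281197	chr11	84085773	84477088	0.39	deletion	male	0	inherited from an unaffected mother	C,B	Exon 8; HPin7-8
284804	chr11	84046644	84539636	0.49	deletion	male	0	de novo constitutive	C,B	Exon 8; HPin7-8
286641	chr11	84291759	84477088	0.19	deletion	male	1	inherited from an unaffected mother	unknown	Intron 7; HPin7
288027	chr11	84046530	84454687	0.41	deletion	male	1	inherited from an unaffected mother	C,B	Exon 8; HPin7-8
288501	chr11	84334017	84595634	0.26	deletion	female	1	unknown	other	Intron 7; HPin7
288842	chr11	84334017	84595634	0.26	deletion	unknown	1	unknown	other	Intron 7; HPin7
289734	chr11	84595575	84907579	0.31	deletion	unknown	2	de novo constitutive	C,B	Exons 5-7
292620	chr11	84046614	84214762	0.17	deletion	female	0	unknown	C	Intron 8; HPin8
300042	chr11	84046614	84419502	0.37	deletion	unknown	0	unknown	C	Exon 8; HPin8
300109	chr11	84419443	84581292	0.16	deletion	unknown	0	inherited from a mother of unknown phenotype	C	Intron 7; HPin7
300111	chr11	84367238	84539665	0.17	deletion	unknown	0	inherited from a mother of unknown phenotype	C	Intron 7; HPin7
1339	chr11	83595987	84489649	0.89	deletion	unknown	1	de novo constitutive	C,B,E	Exons 8-18; HPin7-8
L4	chr11	84003321	84266329	0.26	deletion	unknown	unknown	unknown	P	Exons 8-9; HPin8
L5	chr11	83945764	84214964	0.27	deletion	male	unknown	inherited from an unaffected mother	P	Exons 9-11; HPin8
L6	chr11	83795102	84165325	0.37	deletion	unknown	unknown	de novo constitutive	P	Exons 9-13; HPin8
L7	chr11	84328458	84548416	0.22	deletion	unknown	unknown	de novo constitutive	P	Intron 7; HPin7
L8	chr11	84143697	84312722	0.17	deletion	unknown	1	unknown	P	Exon 8; HPin8
L9	chr11	84111384	84354568	0.24	deletion	unknown	1	unknown	P	Exon 8; HPin8
L11	chr11	83961633	84633847	0.67	deletion	female	unknown	inherited from an unaffected mother	P	Exons 8-11; HPin7-8
L13	chr11	84375859	84521180	0.145	deletion	male	unknown	unknown	P	Intron 7; HPin7
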