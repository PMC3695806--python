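rsid	chrom	pos	gene	source	major_allele	minor_allele	effect_allele	effect_allele_freq	beta	score_set
rs1689800	1	182168885	GLUL,ZNF648	Exome Chip	A	G	A	0.628	0.01	score1
rs13107325	4	103188709	SLC39A8	Exome Chip	C	T	C	0.925	0.02	score1
rs2293889	8	116599199	TRPS1	Sequenom	G	T	G	0.554	0.01	score1
rs2923084	11	10388782	AMPD3	Exome Chip	A	G	A	0.815	0.01	score1
rs7134594	12	110000193	MMAB	Exome Chip	T	C	T	0.520	0.01	score1
rs4759375	12	123796238	SBNO1	Imputed data	C	T	T	0.092	0.02	score1
rs838880	12	125261593	SCARB1	Exome Chip	T	C	C	0.337	0.02	score1
rs16942887	16	67928042	PSKH1	Exome Chip	G	A	A	0.115	0.03	score1
rs881844	17	37810218	STARD3	Imputed data	G	C	G	0.652	0.01	score1
rs4082919	17	76377482	PGS1	Sequenom	G	T	T	0.483	0.01	score1
rs7255436	19	8433196	ANGPTL4	Exome Chip	A	C	A	0.506	0.01	score1
rs737337	19	11347493	DOCK6	Exome Chip	T	C	T	0.900	0.02	score1
rs181362	22	21932068	UBE2L3	Sequenom	C	T	C	0.813	0.01	score1
rs4846914	1	230295691	GALNT2	Sequenom	A	G	A	0.606	0.02	score2
rs17145738	7	72982874	TBL2,BCL7B	Exome Chip	C	T	T	0.124	0.03	score2
rs17482753	8	19832646	LPL	Exome Chip	G	T	T	0.095	0.08	score2
rs17321515	8	126486409	TRIB1	GWAS	A	G	G	0.465	0.02	score2
rs471364	9	15289578	TTC39B	Exome Chip	T	C	T	0.896	0.03	score2
rs3890182	9	107647655	ABCA1	Exome Chip	G	A	G	0.890	0.03	score2
rs174547	11	61570783	FADS1	Exome Chip	T	C	T	0.668	0.03	score2
rs6589566	11	116652423	ZNF259,APOA5	GWAS	A	G	A	0.924	0.05	score2
rs2338104	12	109895168	KCTD10	Exome Chip	G	C	G	0.520	0.03	score2
rs1800588	15	58723675	LIPC	Exome Chip	C	T	T	0.207	0.05	score2
rs3764261	16	56993324	CETP	Exome Chip	C	A	A	0.331	0.1	score2
rs2271293	16	67902070	NUTF2	Exome Chip	G	A	A	0.113	0.03	score2
rs61755018	18	47109955	LIPG	Imputed data	A	G	G	0.007	0.14	score2
rs2967605	19	8469738	RAB11B	Exome Chip	C	T	C	0.812	0.05	score2
rs16988929	20	42904315	GDAP1L1	Imputed data	C	T	T	0.002	0.01	score2
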