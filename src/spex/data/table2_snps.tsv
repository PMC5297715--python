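patient_id	gene	variant_class	consequence	transcript_change	codon_change	chromosome	position	ref_allele	alt_allele	zygosity	population_freq
Patient_01	C1orf100	snp	missense	NM_001012970:p.Tyr78Cys	tAt/tGt	chr1	1000000	A	G	het	
Patient_01	CTNNB1	snp	missense	NM_001098209:p.Asp32Tyr	Gac/Tac	chr3	1010000	G	T	het	
Patient_01	MED12	snp	missense	NM_005120:p.Arg1295Cys	Cgt/Tgt	chrX	1020000	C	T	hom	
Patient_01	MYO1E	snp	missense	NM_004998:p.Ser179Arg	agT/agG	chr15	1030000	T	G	het	
Patient_01	SOS2	snp	missense	NM_006939:p.Leu793Ile	Ctt/Att	chr14	1040000	C	A	het	
Patient_01	UNC13C	snp	missense	NM_001080534:p.Lys1395Met	aAg/aTg	chr15	1050000	A	T	het	
Patient_02	CTNNB1	snp	missense	NM_001098209:p.Asp32Gly	gAc/gGc	chr3	1060000	A	G	het	
Patient_02	H2AFX	snp	missense	NM_002105:p.Leu98Arg	cTg/cGg	chr11	1070000	T	G	het	
Patient_02	NEB	snp	missense	NM_001164507:p.Asp5797Asn	Gat/Aat	chr2	1080000	G	A	het	
Patient_02	SHPK	snp	missense	NM_013276:p.Glu477Asp	gaA/gaC	chr17	1090000	A	C	het	
Patient_03	CTNNB1	snp	missense	NM_001098209:p.Gly34Arg	Gga/Aga	chr3	1100000	G	A	het	
Patient_03	KCMF1	snp	missense	NM_020122:p.Arg257His	cGt/cAt	chr2	1110000	G	A	het	
Patient_05	CTNNB1	snp	missense	NM_001098209:p.Ser37Pro	Tct/Cct	chr3	1120000	T	C	het	
Patient_05	DOCK8	snp	missense	NM_203447:p.Val245Met	Gtg/Atg	chr9	1130000	G	A	het	
Patient_05	LCE1F	snp	missense	NM_178354:p.Arg83His	cGt/cAt	chr1	1140000	G	A	het	
Patient_05	LRCH1	snp	missense	NM_001164211:p.His745Arg	cAt/cGt	chr13	1150000	A	G	het	
Patient_05	N4BP2	snp	missense	NM_018177:p.Thr92Ile	aCc/aTc	chr4	1160000	C	T	het	
Patient_05	PKD1	snp	missense	NM_001009944:p.Arg4249Cys	Cgc/Tgc	chr16	1170000	C	T	het	
Patient_05	PKHD1L1	snp	missense	NM_177531:p.Ile2532Ser	aTt/aGt	chr8	1180000	T	G	het	
Patient_05	PLAU	snp	missense	NM_002658:p.His224Gln	caC/caG	chr10	1190000	C	G	het	
Patient_05	PRHOXNB	snp	missense	NM_001105577:p.Gly116Arg	Ggt/Cgt	chr13	1200000	G	C	het	
Patient_05	TUSC5	snp	missense	NM_172367:p.Ser93Thr	Tcc/Acc	chr17	1210000	T	A	het	
Patient_07	ACTL8	snp	missense	NM_030812:p.Arg48His	cGt/cAt	chr1	1220000	G	A	het	
Patient_07	ADCK5	snp	missense	NM_174922:p.Arg449His	cGc/cAc	chr8	1230000	G	A	het	
Patient_07	ARMCX1	snp	missense	NM_016608:p.Cys144Tyr	tGc/tAc	chrX	1240000	G	A	het	
Patient_07	C16orf62	snp	missense	NM_020314:p.Ala53Glu	gCg/gAg	chr16	1250000	C	A	het	
Patient_07	CCT2	snp	missense	NM_006431:p.Gly98Asp	gGc/gAc	chr12	1260000	G	A	het	
Patient_07	CTNNB1	snp	missense	NM_001098209:p.Ser33Cys	tCt/tGt	chr3	1270000	C	G	het	
Patient_07	WDR62	snp	missense	NM_001083961:p.Val407Ile	Gtt/Att	chr19	1280000	G	A	het	
Patient_08	CLIP1	snp	missense	NM_001247997:p.Ile450Val	Att/Gtt	chr12	1290000	A	G	het	
Patient_08	CTNNB1	snp	missense	NM_001098209:p.Ser37Phe	tCt/tTt	chr3	1300000	C	T	het	
Patient_08	MAP2K1	snp	missense	NM_002755:p.Leu42His	cTt/cAt	chr15	1310000	T	A	het	
Patient_08	NEK8	snp	missense	NM_178170:p.Asp530Asn	Gac/Aac	chr17	1320000	G	A	het	
Patient_08	OR4C6	snp	missense	NM_001004704:p.Phe104Ser	tTc/tCc	chr11	1330000	T	C	het	
Patient_08	ROM1	snp	missense	NM_000327:p.Ala265Glu	gCa/gAa	chr11	1340000	C	A	het	
Patient_08	SETBP1	snp	missense	NM_015559:p.Tyr1327Cys	tAt/tGt	chr18	1350000	A	G	het	
Patient_08	SLC26A10	snp	missense	NM_133489:p.Val488Met	Gtg/Atg	chr12	1360000	G	A	het	
Patient_08	SNTG1	snp	missense	NM_018967:p.Arg202Gln	cGa/cAa	chr8	1370000	G	A	het	
Patient_09	CTNNB1	snp	missense	NM_001098209:p.Ser37Phe	tCt/tTt	chr3	1380000	C	T	het	
Patient_09	DDX42	snp	missense	NM_007372:p.Thr581Ala	Acc/Gcc	chr17	1390000	A	G	het	
Patient_09	TBP	snp	missense	NM_003194:p.Thr106Ala	Acg/Gcg	chr6	1400000	A	G	het	
Patient_09	USP9X	snp	missense	NM_001039590:p.Asn2098Ser	aAt/aGt	chrX	1410000	A	G	het	
Patient_10	CTNNB1	snp	missense	NM_001098209:p.Ser33Phe	tCt/tTt	chr3	1420000	C	T	het	
Patient_10	FAM89A	snp	missense	NM_198552:p.Ser175Cys	tCc/tGc	chr1	1430000	C	G	het	
Patient_11	BCAP31	snp	missense	NM_001139457:p.Ile190Val	Att/Gtt	chrX	1440000	A	G	het	
Patient_11	BHMT	snp	missense	NM_001713:p.Asp105Asn	Gac/Aac	chr5	1450000	G	A	het	
Patient_11	C16orf3	snp	missense	NM_001214:p.Val60Ile	Gta/Ata	chr16	1460000	G	A	het	
Patient_11	C16orf3	snp	missense	NM_001214:p.Ser57Gly	Agc/Ggc	chr16	1470000	A	G	het	
Patient_11	COL5A3	snp	missense	NM_015719:p.Gly533Val	gGa/gTa	chr19	1480000	G	T	het	
Patient_11	CRAMP1L	snp	missense	NM_020825:p.Pro818Thr	Ccc/Acc	chr16	1490000	C	A	het	
Patient_11	CTNNB1	snp	missense	NM_001098209:p.Asp32Tyr	Gac/Tac	chr3	1500000	G	T	het	
Patient_11	E2F7	snp	missense	NM_203394:p.Phe873Val	Ttt/Gtt	chr12	1510000	T	G	het	
Patient_11	FCGBP	snp	missense	NM_003890:p.Gly4778Asp	gGc/gAc	chr19	1520000	G	A	het	
Patient_11	FGGY	snp	missense	NM_001113411:p.Ser21Asn	aGt/aAt	chr1	1530000	G	A	het	
Patient_11	KEL	snp	missense	NM_000420:p.Arg393Gln	cGg/cAg	chr7	1540000	G	A	het	
Patient_11	KIAA0586	snp	missense	NM_001244189:p.Lys953Ile	aAa/aTa	chr14	1550000	A	T	het	
Patient_11	KRT16	snp	missense	NM_005557:p.Gly69Cys	Ggc/Tgc	chr17	1560000	G	T	het	
Patient_11	PEX10	snp	missense	NM_153818:p.Leu221His	cTc/cAc	chr1	1570000	T	A	het	
Patient_11	PTOV1	snp	missense	NM_017432:p.Lys212Met	aAg/aTg	chr19	1580000	A	T	het	
Patient_11	SIRPB2	snp	missense	NM_001122962:p.Gly94Arg	Ggg/Agg	chr20	1590000	G	A	het	
Patient_11	SPINLW1-WFDC6	snp	missense	NM_001198986:p.Glu141Lys	Gaa/Aaa	chr20	1600000	G	A	het	
Patient_11	THAP4	snp	missense	NM_015963:p.Gly111Ser	Ggt/Agt	chr2	1610000	G	A	het	
Patient_11	TMEM99	snp	missense	NM_001195386:p.Asp195Asn	Gac/Aac	chr17	1620000	G	A	het	
Patient_11	TYR	snp	missense	NM_000372:p.Thr292Met	aCg/aTg	chr11	1630000	C	T	het	
Patient_11	UMODL1	snp	missense	NM_173568:p.Asp814Glu	gaC/gaG	chr21	1640000	C	G	het	
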