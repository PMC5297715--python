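patient_id	gene	variant_class	consequence	transcript_change	codon_change	chromosome	position	ref_allele	alt_allele	zygosity	population_freq	impact	category
cohort	AHDC1	indel	frameshift			chr1	2000000	T	TG	het		High	FS
cohort	LRRIQ3	indel	frameshift			chr1	2010000	G	GT	het		High	FS
cohort	NOC3L	indel	frameshift			chr10	2020000	AT	A	het		High	FS
cohort	TFAM	indel	frameshift			chr10	2030000	CA	C	het		High	FS
cohort	TDG	indel	frameshift			chr12	2040000	G	GA	het		High	FS
cohort	CCNK	indel	frameshift			chr14	2050000	G	GC	het		High	FS
cohort	PAPOLA	indel	frameshift			chr14	2060000	TG	T	het		High	FS
cohort	IRX5	indel	frameshift			chr16	2070000	AGG	A	het		High	FS
cohort	ACSF2	indel	frameshift			chr17	2080000	T	TAA	het		High	FS
cohort	KRT10	indel	frameshift			chr17	2090000	CCGCCG	C	het		High	FS
cohort	KRT10	indel	frameshift			chr17	2100000	TG	T	het		High	FS
cohort	CAPN12	indel	frameshift			chr19	2110000	G	GC	het		High	FS
cohort	KCNC3	indel	frameshift			chr19	2120000	C	CG	het		High	FS
cohort	SNED1	indel	frameshift			chr2	2130000	A	AC	het		High	FS
cohort	C20orf132	indel	frameshift			chr20	2140000	GACCT	G	het		High	FS
cohort	C20orf132	indel	frameshift			chr20	2150000	GC	G	het		High	FS
cohort	C20orf132	indel	frameshift			chr20	2160000	GAGGAGTT	G	het		High	FS
cohort	C20orf132	indel	frameshift			chr20	2170000	CG	C	het		High	FS
cohort	C20orf132	indel	frameshift			chr20	2180000	TGG	T	het		High	FS
cohort	TBP	indel	frameshift			chr6	2190000	AGC	A	het		High	FS
cohort	TBP	indel	frameshift			chr6	2200000	AG	A	het		High	FS
cohort	TFB1M	indel	frameshift			chr6	2210000	CAA	C	het		High	FS
cohort	PHF2	indel	frameshift			chr9	2220000	A	AG	het		High	FS
cohort	PLXNA3	indel	frameshift			chrX	2230000	T	TG	het		High	FS
cohort	RBM10	indel	frameshift			chrX	2240000	CA	C	het		High	FS
cohort	KRI1	indel	splice			chr19	2250000	CCATCA	C	het		High	SSD
cohort	KRI1	indel	splice			chr19	2260000	CCATCA	C	het		High	SSD
cohort	SCUBE2	indel	inframe			chr11	2270000	GGCA	G	het		Moderate	C&D
cohort	ATXN2	indel	inframe			chr12	2280000	GGCT	G	het		Moderate	C&D
cohort	MAP3K9	indel	inframe			chr14	2290000	GCCT	G	het		Moderate	C&D
cohort	SAFB2	indel	inframe			chr19	2300000	GTAC	G	het		Moderate	C&D
cohort	GIGYF2	indel	inframe			chr2	2310000	CACA	C	het		Moderate	C&D
cohort	TPRN	indel	inframe			chr9	2320000	TTCC	T	het		Moderate	C&D
cohort	AR	indel	inframe			chrX	2330000	AAGAGACTAGCCCCAG	A	het		Moderate	C&D
cohort	KRTAP5-8	indel	inframe			chr11	2340000	T	TCCG	het		Moderate	C&I
cohort	ATXN3	indel	inframe			chr14	2350000	C	CCTG	het		Moderate	C&I
cohort	IRF2BPL	indel	inframe			chr14	2360000	C	CTGCTGT	het		Moderate	C&I
cohort	HTT	indel	inframe			chr4	2370000	A	AACAGCC	het		Moderate	C&I
cohort	ATAD2	indel	inframe			chr8	2380000	A	ATCG	het		Moderate	C&I
cohort	APOBR	indel	inframe			chr16	2390000	TGGGACAGCCTCAGGAGGGGAGGAGGCC	T	het		Moderate	CD
cohort	KDM6B	indel	inframe			chr17	2400000	TCAC	T	het		Moderate	CD
cohort	MBD2	indel	inframe			chr18	2410000	CGCA	C	het		Moderate	CD
cohort	ARID3A	indel	inframe			chr19	2420000	GGGA	G	het		Moderate	CD
cohort	ADAM29	indel	inframe			chr4	2430000	GTGACACCCTCCCAGAGGCAACCTCAGT	G	het		Moderate	CD
cohort	KCNQ5	indel	inframe			chr6	2440000	AGCG	A	het		Moderate	CD
cohort	TBP	indel	inframe			chr6	2450000	GCAA	G	het		Moderate	CD
cohort	RNF20	indel	inframe			chr9	2460000	TGTTGACTCTGAAGACTCA	T	het		Moderate	CD
cohort	C10orf140	indel	inframe			chr10	2470000	C	CCCTCCT	het		Moderate	CI
cohort	EP400	indel	inframe			chr12	2480000	A	ACAG	het		Moderate	CI
cohort	EP400	indel	inframe			chr12	2490000	A	ACAG	het		Moderate	CI
cohort	EP400	indel	inframe			chr12	2500000	G	GCAA	het		Moderate	CI
cohort	KRTAP4-5	indel	inframe			chr17	2510000	T	TGGCAGCAGCTGGGGC	het		Moderate	CI
cohort	ZNF814	indel	inframe			chr19	2520000	C	CATA	het		Moderate	CI
cohort	HTT	indel	inframe			chr4	2530000	A	ACCGCCGCCG	het		Moderate	CI
cohort	TBP	indel	inframe			chr6	2540000	A	ACAG	het		Moderate	CI
cohort	TBP	indel	inframe			chr6	2550000	A	ACAG	het		Moderate	CI
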