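# Synthetic stand-in for the study's 59-variant trackable-mutation list:
# the 3 noise-excluded variants carry their printed hg19 coordinates; the other 56
# records are invented placeholders with a realistic SNV/indel mix.
chrom	pos	ref	alt	gene	label
chr17	74732959	G	T	SRSF2	SRSF2_p.Pro95His
chr11	32417910	G	T	WT1	WT1_p.Pro95His
chr21	36252869	C	A	RUNX1	RUNX1_p.Gly165Cys
chr2	18231812	G	GT	DNMT3A	DNMT3A_ins_4
chr13	61641778	C	A	FLT3	FLT3_snv_5
chr2	68823649	AACT	A	IDH1	IDH1_del_6
chr15	85099843	T	TGCTCA	IDH2	IDH2_ins_7
chr9	27957000	T	C	JAK2	JAK2_snv_8
chr12	130521694	T	TCAGAG	KRAS	KRAS_ins_9
chr5	45388676	ATA	A	NPM1	NPM1_del_10
chr1	119965269	TTGAGC	T	NRAS	NRAS_del_11
chr2	192362248	A	ACCAG	SF3B1	SF3B1_ins_12
chr17	102313658	G	GA	TP53	TP53_ins_13
chr21	164085303	A	ATGTAC	U2AF1	U2AF1_ins_14
chr11	2644572	CTCCTG	C	WT1	WT1_del_15
chr20	24736623	A	G	ASXL1	ASXL1_snv_16
chr19	137912058	G	C	CALR	CALR_snv_17
chr1	192503643	G	A	CSF3R	CSF3R_snv_18
chr4	167890351	T	G	KIT	KIT_snv_19
chr1	141543979	G	C	MPL	MPL_snv_20
chr18	173878260	GGAGGG	G	SETBP1	SETBP1_del_21
chr17	57529934	G	GCA	SRSF2	SRSF2_ins_22
chr21	3263706	T	TG	RUNX1	RUNX1_ins_23
chr7	41885056	TGCCCA	T	BRAF	BRAF_del_24
chr3	181782063	T	G	MYD88	MYD88_snv_25
chr2	106923663	GTAGCTA	G	DNMT3A	DNMT3A_del_26
chr13	143405828	T	TCTACGT	FLT3	FLT3_ins_27
chr2	12980177	G	T	IDH1	IDH1_snv_28
chr15	176619219	T	G	IDH2	IDH2_snv_29
chr9	106619072	GT	G	JAK2	JAK2_del_30
chr12	123261247	TCGACTG	T	KRAS	KRAS_del_31
chr5	147518482	A	C	NPM1	NPM1_snv_32
chr1	157747631	GC	G	NRAS	NRAS_del_33
chr2	178022147	T	TAA	SF3B1	SF3B1_ins_34
chr17	145279341	C	A	TP53	TP53_snv_35
chr21	130757224	A	T	U2AF1	U2AF1_snv_36
chr11	111814080	A	G	WT1	WT1_snv_37
chr20	129767034	G	A	ASXL1	ASXL1_snv_38
chr19	5418751	GCAGT	G	CALR	CALR_del_39
chr1	190795823	AAA	A	CSF3R	CSF3R_del_40
chr4	60504616	A	ATAG	KIT	KIT_ins_41
chr1	192810849	C	CTGAA	MPL	MPL_ins_42
chr18	145903976	CCTTTAA	C	SETBP1	SETBP1_del_43
chr17	57410911	CTA	C	SRSF2	SRSF2_del_44
chr21	16285761	A	ATTGCAT	RUNX1	RUNX1_ins_45
chr7	121379056	C	CCCTTTT	BRAF	BRAF_ins_46
chr3	122767831	GTGTCA	G	MYD88	MYD88_del_47
chr2	179662434	G	A	DNMT3A	DNMT3A_snv_48
chr13	138538861	G	A	FLT3	FLT3_snv_49
chr2	65782453	A	G	IDH1	IDH1_snv_50
chr15	191883962	GATTAGG	G	IDH2	IDH2_del_51
chr9	53255251	CCTCTAC	C	JAK2	JAK2_del_52
chr12	56596439	G	GTAGGA	KRAS	KRAS_ins_53
chr5	77628867	A	G	NPM1	NPM1_snv_54
chr1	99443463	T	A	NRAS	NRAS_snv_55
chr2	51995873	G	C	SF3B1	SF3B1_snv_56
chr17	72024337	CCCA	C	TP53	TP53_del_57
chr21	32388594	GCGCGC	G	U2AF1	U2AF1_del_58
chr11	167524102	C	G	WT1	WT1_snv_59
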