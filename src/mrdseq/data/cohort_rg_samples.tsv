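patient_id	source	days_before_relapse	group	str_status	ngs_status	mfc_status
RG01	BM	21	RG	Negative	Positive	Negative
RG01	PB	21	RG	Negative	Negative	NotPerformed
RG02	BM	38	RG	Negative	Positive	NotPerformed
RG02	BM	119	RG	Negative	Negative	Negative
RG03	BM	44	RG	Negative	Positive	Negative
RG04	BM	31	RG	Negative	Positive	NotPerformed
RG04	PB	31	RG	Negative	Positive	NotPerformed
RG05	BM	41	RG	Negative	Negative	NotPerformed
RG06	BM	49	RG	Negative	Negative	NotPerformed
RG07	BM	43	RG	Negative	Positive	Negative
RG07	PB	43	RG	Negative	Negative	NotPerformed
RG08	BM	50	RG	Negative	Positive	NotPerformed
RG08	PB	50	RG	Negative	Negative	NotPerformed
RG08	BM	98	RG	Negative	Negative	NotPerformed
RG08	PB	98	RG	Negative	Negative	NotPerformed
RG09	BM	56	RG	Negative	Negative	NotPerformed
RG10	BM	60	RG	Negative	Negative	Negative
RG11	BM	72	RG	Negative	Positive	NotPerformed
RG11	BM	136	RG	Negative	Negative	NotPerformed
RG12	BM	61	RG	Negative	Positive	NotPerformed
RG12	PB	61	RG	Negative	Negative	NotPerformed
RG12	BM	117	RG	Negative	Negative	NotPerformed
RG13	BM	95	RG	Negative	Negative	NotPerformed
RG14	BM	99	RG	Negative	Negative	NotPerformed
RG15	PB	84	RG	Negative	Negative	NotPerformed
RG16	PB	32	RG	Negative	Positive	NotPerformed
RG16	BM	77	RG	Negative	Positive	NotPerformed
RG16	PB	77	RG	Negative	Positive	NotPerformed
RG16	BM	105	RG	Negative	Negative	NotPerformed
RG17	BM	28	RG	Negative	Negative	NotPerformed
RG18	PB	27	RG	Negative	Negative	NotPerformed
RG18	BM	69	RG	Negative	Positive	Negative
RG18	PB	69	RG	Negative	Negative	NotPerformed
RG19	PB	48	RG	Negative	Positive	NotPerformed
RG19	BM	76	RG	Negative	Positive	NotPerformed
RG19	BM	147	RG	Negative	Negative	NotPerformed
RG20	PB	49	RG	Negative	Positive	NotPerformed
RG20	PB	204	RG	Negative	Negative	NotPerformed
RG21	BM	79	RG	Negative	Negative	NotPerformed
RG22	BM	69	RG	Negative	Positive	NotPerformed
RG22	BM	147	RG	Negative	Negative	NotPerformed
RG22	PB	147	RG	Negative	Negative	NotPerformed
RG23	PB	21	RG	Negative	Positive	NotPerformed
RG23	BM	86	RG	Negative	Negative	NotPerformed
RG24	BM	32	RG	Negative	Negative	NotPerformed
RG25	BM	46	RG	Negative	Positive	NotPerformed
RG25	BM	105	RG	Negative	Negative	Negative
RG26	BM	44	RG	Negative	Negative	NotPerformed
RG27	PB	32	RG	Negative	Positive	NotPerformed
RG27	BM	66	RG	Negative	Positive	NotPerformed
RG28	PB	61	RG	Negative	Positive	NotPerformed
RG28	PB	117	RG	Negative	Negative	NotPerformed
RG29	PB	52	RG	Negative	Negative	NotPerformed
RG29	BM	91	RG	Negative	Negative	NotPerformed
RG30	PB	35	RG	Negative	Positive	NotPerformed
RG30	BM	74	RG	Negative	Positive	Negative
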