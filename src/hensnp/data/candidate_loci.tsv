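snp_id	trait	location	chrom	pos	genotypes	n_aa	n_ab	n_bb	freq_aa	freq_ab	freq_bb	ea	oa	ea_freq_printed	gene
AX-75268181	Tib_BMD	intragenic	1	139001157	CC/CT/TT	392	96	36	0.75	0.18	0.07	T	C	0.16	MCF2L
AX-76044166	Tib_BBS	intragenic	2	15440861	AA/AG/GG	421	63	40	0.80	0.12	0.08	G	A	0.14	MPP7
AX-80813610	Tib_BMD	downstream	2	23056581	CC/CG/GG	339	113	72	0.65	0.22	0.13	G	C	0.25	CALCR
AX-76099065	Tib_BMD	intragenic	2	46101680	GG/GA/AA	392	77	55	0.75	0.15	0.10	A	G	0.18	SFRP4
AX-76601713	Tib_BBS	intragenic	3	10617925	AA/AG/GG	265	102	157	0.51	0.19	0.30	G	A	0.40	ACTR2
AX-77276717	Tib_BBS	intragenic	3	19498104	GG/GA/AA	322	145	57	0.61	0.28	0.11	A	G	0.25	TGFB2
AX-76491534	Tib_BBS	intragenic	3	49027160	AA/AG/GG	432	62	30	0.82	0.12	0.06	G	A	0.12	CCDC170
AX-76772658	Tib_BBS/Hum_BBS	intragenic	5	11438677	TT/TC/CC	219	199	109	0.41	0.38	0.21	C	T	0.40	SOX6
AX-77113061	Tib_BMD	upstream	8	5889886	GG/AG/AA	202	156	166	0.38	0.30	0.32	A	G	0.47	TMCO1
AX-77091655	Hum_BBS/Hum_BMD	upstream	8	24931025	CC/CA/AA	286	139	99	0.54	0.27	0.19	A	C	0.32	PODN
AX-75597497	Hum_BBS	downstream	10	19108829	AA/AG/GG	376	124	24	0.72	0.24	0.04	G	A	0.16	SMAD6
AX-75677174	Tib_BMD	intragenic	11	10044055	CC/CT/TT	377	107	40	0.72	0.20	0.08	T	C	0.18	GPATCH1
AX-75711229	Tib_BBS	intragenic	12	3804145	GG/AG/AA	459	58	7	0.88	0.11	0.01	A	G	0.07	ASPN
AX-75913642	Tib_BBS	upstream	18	8793585	GG/AG/AA	451	61	12	0.86	0.12	0.02	A	G	0.08	SOX9
AX-76351785	Hum_BBS	intragenic	27	3497444	CC/CT/TT	316	138	70	0.61	0.26	0.13	T	C	0.26	WNT9B
AX-76351898	Hum_BMD	downstream	27	3518924	GG/GA/AA	483	31	10	0.92	0.06	0.02	A	G	0.05	WNT3
AX-76351899	Hum_BMD	downstream	27	3519091	TT/TC/CC	483	31	10	0.92	0.06	0.02	C	T	0.05	WNT3
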