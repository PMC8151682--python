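snp_id	trait	gene	lsm_AA	se_AA	lsm_AB	se_AB	lsm_BB	se_BB
AX-76044166	Tib_BBS	MPP7	155.33	2.26	145.80	5.85	172.76	7.25
AX-76601713	Tib_BBS	ACTR2	162.77	3.08	156.79	3.81	143.10	3.79
AX-77276717	Tib_BBS	TGFB2	153.42	2.25	157.05	3.06	163.72	5.10
AX-76491534	Tib_BBS	CCDC170	159.13	2.19	144.04	6.28	127.83	8.09
AX-76772658	Tib_BBS	SOX6	149.06	2.65	158.53	2.58	163.29	3.90
AX-75711229	Tib_BBS	ASPN	155.14	1.94	154.78	5.29	188.53	13.11
AX-75913642	Tib_BBS	SOX9	157.50	1.93	148.13	4.83	124.13	10.37
AX-76772658	Hum_BBS	SOX6	127.04	2.51	116.24	2.46	119.38	3.71
AX-77091655	Hum_BBS	PODN	118.01	2.31	120.73	3.04	132.21	3.73
AX-75597497	Hum_BBS	SMAD6	122.16	2.08	123.48	3.64	98.16	6.97
AX-76351785	Hum_BBS	WNT9B	115.73	2.19	124.86	3.05	139.61	4.34
AX-75268181	Tib_BMD	MCF2L	0.263	0.003	0.253	0.005	0.228	0.008
AX-80813610	Tib_BMD	CALCR	0.256	0.003	0.258	0.005	0.273	0.006
AX-76099065	Tib_BMD	SFRP4	0.261	0.003	0.265	0.008	0.235	0.009
AX-77113061	Tib_BMD	TMCO1	0.246	0.005	0.267	0.004	0.266	0.004
AX-75677174	Tib_BMD	GPATCH1	0.254	0.003	0.269	0.005	0.278	0.007
AX-77091655	Hum_BMD	PODN	0.164	0.002	0.167	0.003	0.178	0.003
AX-76351898	Hum_BMD	WNT3	0.166	0.002	0.176	0.006	0.206	0.010
AX-76351899	Hum_BMD	WNT3	0.166	0.002	0.176	0.006	0.206	0.010
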