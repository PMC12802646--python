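SNG9	synthetic stand-in senescence gene set	SYN2710	SYN0852	SYN0035	SYN0326	SYN2395	CXCL8	SYN0643	SYN2835	SYN2591	SYN1686	SYN1240	SYN0641	SYN0149	SYN2494	SYN1197	SYN0299	SYN2181	JUN	SYN2450	SYN0925	SYN1557	SYN1069	SYN0511	SYN2562	SYN0634	SYN2592	SYN0403	SYN1517	SYN1103	SYN0506	SYN1667	SYN2911	SYN2783	SYN0615	SYN1552	SYN1811	SYN1274	SYN2523	SYN1524	GDF15	SYN2635	SYN1727	SYN1469	TIMP1	SYN1590	SYN0466	SYN1278	SYN0496	SYN2226	SYN2352	SYN0116	MMP1	SYN2422	SYN1434	SYN0319	SYN2004	SYN0218	SYN0093	SYN0921	SYN0358	SYN1383	CXCL2	SYN0882	SYN1154	GLB1	SYN0037	SYN1627	SYN0797	SYN1651	SYN1847	IGF1	SYN1071	SYN0186	SYN1118	SYN2657	SYN2388	SYN2782	SYN1628	SYN1429	SYN1520	SYN0267	SYN1392	SYN0104	SYN1353	SYN0595	SYN0395	SYN2907	SYN1090	SYN2236	SYN1086	SYN2889	SYN1258	SYN0051	SYN2280	SYN2002	SYN0586	SYN0280	SYN1536	SYN1831	SYN0753	SYN2248	SYN1371	SYN1755	SYN0077	SYN0939	CDK1	SYN1412	SYN0261	SYN0171	SYN0966	SYN2353	SYN2468	NFKB1	CXCL1	SYN0373	SYN1279	SYN2582	SYN0544	SYN1933	SYN2486	SYN1457	CDKN2A	SYN0715	SYN0120	SYN2208	SYN0744	SYN2611	SYN2195	SYN1458	SYN2453	SYN0809	SYN0250	EZH2	SYN0421	CDKN2B	SYN2329	SYN2010	SYN2703	SYN2577	SYN1916	SYN0527	CDKN1A	SYN2370	SYN1387	B2M	SYN2568	SYN2448	SYN2532	SYN2011	SYN0100	SYN1006	SYN0492	SYN2574	SYN0313	SYN2400	SYN0842	SYN0500	SYN2203	SYN0814	SYN0600	SYN2923
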