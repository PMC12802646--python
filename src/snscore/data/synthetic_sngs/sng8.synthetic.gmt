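SNG8	synthetic stand-in senescence gene set	SYN2887	SYN0569	SYN2587	SYN2313	SYN0368	SYN1989	SYN2374	SYN2273	SYN2181	SYN2909	SYN2419	CDKN2A	SYN1519	SYN2144	SYN2780	GLB1	SYN1196	SYN1803	SYN2042	TGFB1	SYN1887	SYN2754	SYN2139	SYN2745	SYN1085	SYN0291	SYN0165	SYN1583	SYN2457	SYN0499	SYN2524	SYN2714	SYN1099	SYN2650	SYN1478	SYN1102	SYN0043	SYN2385	SYN2376	SYN1098	SYN2779	SYN1336	SYN1830	SYN1376	SYN2247	SYN2220	SYN0664	SYN2807	SYN1125	SYN0845	SYN1368	SYN2705	SYN2486	SYN1530	SYN2305	SYN2182	SYN1027	SYN1089	SYN1047	SYN1760	CXCL2	SYN1697	SYN0122	SYN1590	SYN2496	SYN0005	SYN2799	CCL2	SYN1696	SYN2635	SYN0106	SYN0788	SYN1836	SYN0120	SYN0666	SYN2595	CDKN1A	SYN1963	SYN0670	SYN1349	SYN2415	SYN0833	SYN2383	SYN1286	SYN2414	TIMP2	SYN0010	SYN1720	SYN0698	SYN2920	SYN2117	SYN2750	SYN2549	SYN1551	SYN1057	SYN1929	SYN2107	SYN1259	SYN1597	SYN0332	SYN2638	SYN0348	SYN0313	SYN1667	SYN1701	SYN0248	SYN0705	SYN1427	SYN2902	SYN1606	SYN2614	SYN0022	SYN2539	TP53	SYN2427	SYN2014	EZH2	SYN0656	SYN1157	SYN1344	SYN2673	SYN2084	SYN1863	SYN0936	SYN1912	SYN1178	SYN0991	SYN1712	SYN0780	SYN2604	SYN2255	SYN0154	SYN1982	SYN0794	SYN0496	SYN0778	SYN1665	CCNB1	SYN1254	SYN0461	SYN1452	SYN1804	SYN0198	SYN1112	SYN2672	SYN1759	SYN0561	SYN1657	SYN1922	SYN2625	SYN0425	SYN1275	SYN0364	SYN1503	SYN2683	SYN1115	SYN2550	IL6	SYN0646	SYN2409	SYN0356	MMP3	SYN1640	SYN1317	SYN2719	SYN1023	SYN1150	SYN1350	SYN0635	SYN2781	SYN1140	SYN0151	SYN1576	SYN2408	ICAM1	SYN2776	SYN1707	SYN1213	SYN2373	SYN2191	SYN2467	SYN2024	SYN1977	SYN0517	SYN2105	SYN2150	SYN0859	JUN	SYN0371	SYN1546	SYN0642	SYN1833	SYN1554	SYN1735	SYN2893	SYN2824	SYN1074	SYN2926	SYN0505	SYN0638	SYN1299	SYN1682	SYN1231	SYN1015	SYN0790	SYN0657	FAS	SYN1972	SYN0571	CXCL8	SYN1818	SYN1500	TNFRSF10C	SYN1323	SYN2623	SYN1938	SYN2421	SYN2395	SYN1022	SYN2004	SYN0758	IGFBP5	CXCL1	SYN2777	SYN0419	SYN0624
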