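SNG7	synthetic stand-in senescence gene set	SYN0504	SYN1439	SYN2252	SYN2366	SYN1442	SYN2149	SYN2279	SYN2316	SYN2088	SYN1518	SYN0315	SYN0424	SYN1973	SYN0662	SYN2881	SYN0902	SYN1716	SYN1451	SYN0001	SYN2717	CDKN1A	SYN1912	SYN2473	SYN1537	SYN1834	SYN0904	SYN0283	SYN0411	SYN0985	TIMP1	SYN2734	SYN1368	SYN2238	SYN1846	SYN2018	SYN1890	SYN1221	SYN0408	SYN1042	SYN1769	SYN1878	SYN1469	SYN0465	SYN0748	SYN2295	SYN0243	MMP1	SYN1564	SYN2802	SYN0405	SYN2390	SYN2776	SYN2698	SYN0861	SYN0351	SYN1859	SYN0803	SYN0755	JUN	SYN2664	SYN0615	SYN1026	SYN0663	SYN1274	SYN1081	SERPINE1	SYN0392	SYN1971	SYN0144	SYN0336	SYN2418	SYN1463	SYN2171	SYN2812	SYN1547	SYN1867	SYN0146	SYN0679	SYN1935	SYN2513	SYN1300	SYN2655	SYN1175	SYN0040	SYN2723	SYN1841	SYN1870	SYN1293	SYN2678	SYN1854	SYN1737	SYN0038	SYN1183	SYN1185	CXCL1	SYN1265	SYN0094	IGFBP5	SYN1064	SYN2622	FAS	SYN0835	SYN0695	SYN0578	SYN0621	SYN2469	SYN1807	SYN2509	SYN0778	SYN1287	IL1A	SYN1416	SYN2068	SYN2327	SYN0547	SYN0677	SYN0728	SYN2548	SYN2248	SYN1000	CCNB1	SYN2048	SYN0758	SYN2878	SYN2884	SYN2789	SYN1289	SYN2708	SYN2278	SYN2361	SYN2016	SYN2347	SYN0432	SYN1143	SYN2183	SYN0339	SYN1105	SYN0526	SYN0233	SYN0223	SYN1417	SYN1276	SYN0099	SYN1045	SYN2844	SYN1199	SYN2349	SYN0033	CCL20	SYN1625	SYN2656	SYN1540	SYN2478	SYN2858	SYN0462	SYN1340	SYN1516	SYN1217	SYN2742	STAT1	SYN2620	SYN2733	SYN0601	SYN0853	SYN0788	SYN0496	SYN0860	SYN2819	SYN1873	SYN2210	SYN1705	SYN0769	SYN0383	SYN0718	SYN0274	SYN0485	SYN0115	SYN0875	SYN0574	SYN0950	SYN2209	SYN0352	SYN2243	SYN0201	SYN2308	SYN2240	SYN1437	SYN2006	SYN0588	SYN2593	SYN1684	SYN2348	SYN0450	SYN0765	SYN2765	SYN1638	EZH2	SYN1244	SYN2540	SYN2284	SYN2606	SYN0057	SYN1238	SYN1382	SYN1942	SYN2570	SYN2385	SYN2810	SYN1148	SYN1399	SYN0198	SYN2565	SYN0599	SYN1326	SYN2178	SYN0692	SYN1215	SYN0799	SYN0856	SYN1743	SYN1600	SYN0174	SYN0282	GDF15	SYN1630	SYN2719	SYN2875	SYN2863	SYN1494	SYN0633	LMNB1	IL1B	SYN2307	SYN0976	SYN2273	NFKB1	SYN2467	SYN0456	SYN0449	SYN1533	SYN2813	SYN2439	SYN0290	SYN2694	SYN0361	SYN2674	SYN2471	SYN0768	SYN0958	SYN2816	SYN2494	MMP3	SYN2868	SYN0246	SYN2044	SYN1652	SYN1514	SYN2516	SYN2332	SYN2013	SYN1281	SYN0213	SYN1774	SYN0827	SYN0483	IGFBP3	SYN2800	SYN2914	SYN1719	SYN1093	SYN1683	SYN0421	SYN2285	SYN0325	SYN2574	SYN1301
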