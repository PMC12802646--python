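gene	direction
SYN0504	induces
SYN1439	inhibits
SYN2252	induces
SYN2366	induces
SYN1442	induces
SYN2149	induces
SYN2279	inhibits
SYN2316	induces
SYN2088	induces
SYN1518	inhibits
SYN0315	induces
SYN0424	inhibits
SYN1973	unknown
SYN0662	inhibits
SYN2881	induces
SYN0902	induces
SYN1716	unknown
SYN1451	induces
SYN0001	inhibits
SYN2717	inhibits
CDKN1A	induces
SYN1912	unknown
SYN2473	induces
SYN1537	induces
SYN1834	inhibits
SYN0904	inhibits
SYN0283	inhibits
SYN0411	induces
SYN0985	induces
TIMP1	induces
SYN2734	unknown
SYN1368	unknown
SYN2238	induces
SYN1846	unknown
SYN2018	induces
SYN1890	induces
SYN1221	induces
SYN0408	induces
SYN1042	induces
SYN1769	induces
SYN1878	unknown
SYN1469	induces
SYN0465	induces
SYN0748	induces
SYN2295	inhibits
SYN0243	induces
MMP1	induces
SYN1564	inhibits
SYN2802	induces
SYN0405	induces
SYN2390	induces
SYN2776	inhibits
SYN2698	inhibits
SYN0861	induces
SYN0351	inhibits
SYN1859	unknown
SYN0803	induces
SYN0755	induces
JUN	induces
SYN2664	induces
SYN0615	induces
SYN1026	induces
SYN0663	inhibits
SYN1274	induces
SYN1081	induces
SERPINE1	induces
SYN0392	induces
SYN1971	induces
SYN0144	inhibits
SYN0336	inhibits
SYN2418	induces
SYN1463	inhibits
SYN2171	induces
SYN2812	unknown
SYN1547	induces
SYN1867	induces
SYN0146	induces
SYN0679	induces
SYN1935	induces
SYN2513	induces
SYN1300	induces
SYN2655	inhibits
SYN1175	inhibits
SYN0040	inhibits
SYN2723	induces
SYN1841	inhibits
SYN1870	induces
SYN1293	unknown
SYN2678	induces
SYN1854	unknown
SYN1737	induces
SYN0038	induces
SYN1183	induces
SYN1185	induces
CXCL1	induces
SYN1265	induces
SYN0094	unknown
IGFBP5	induces
SYN1064	unknown
SYN2622	induces
FAS	induces
SYN0835	induces
SYN0695	induces
SYN0578	induces
SYN0621	induces
SYN2469	induces
SYN1807	induces
SYN2509	inhibits
SYN0778	induces
SYN1287	induces
IL1A	induces
SYN1416	inhibits
SYN2068	inhibits
SYN2327	inhibits
SYN0547	induces
SYN0677	induces
SYN0728	inhibits
SYN2548	inhibits
SYN2248	unknown
SYN1000	inhibits
CCNB1	inhibits
SYN2048	induces
SYN0758	induces
SYN2878	induces
SYN2884	induces
SYN2789	inhibits
SYN1289	unknown
SYN2708	induces
SYN2278	induces
SYN2361	induces
SYN2016	unknown
SYN2347	unknown
SYN0432	induces
SYN1143	unknown
SYN2183	inhibits
SYN0339	induces
SYN1105	induces
SYN0526	inhibits
SYN0233	induces
SYN0223	inhibits
SYN1417	unknown
SYN1276	induces
SYN0099	induces
SYN1045	induces
SYN2844	unknown
SYN1199	induces
SYN2349	inhibits
SYN0033	unknown
CCL20	induces
SYN1625	unknown
SYN2656	unknown
SYN1540	induces
SYN2478	induces
SYN2858	induces
SYN0462	unknown
SYN1340	inhibits
SYN1516	unknown
SYN1217	induces
SYN2742	induces
STAT1	induces
SYN2620	induces
SYN2733	inhibits
SYN0601	induces
SYN0853	inhibits
SYN0788	unknown
SYN0496	unknown
SYN0860	induces
SYN2819	induces
SYN1873	induces
SYN2210	induces
SYN1705	inhibits
SYN0769	induces
SYN0383	inhibits
SYN0718	inhibits
SYN0274	unknown
SYN0485	inhibits
SYN0115	inhibits
SYN0875	induces
SYN0574	induces
SYN0950	induces
SYN2209	induces
SYN0352	induces
SYN2243	induces
SYN0201	induces
SYN2308	induces
SYN2240	unknown
SYN1437	inhibits
SYN2006	inhibits
SYN0588	inhibits
SYN2593	induces
SYN1684	induces
SYN2348	induces
SYN0450	unknown
SYN0765	induces
SYN2765	induces
SYN1638	inhibits
EZH2	inhibits
SYN1244	inhibits
SYN2540	induces
SYN2284	unknown
SYN2606	induces
SYN0057	induces
SYN1238	unknown
SYN1382	unknown
SYN1942	induces
SYN2570	unknown
SYN2385	inhibits
SYN2810	unknown
SYN1148	induces
SYN1399	induces
SYN0198	unknown
SYN2565	induces
SYN0599	inhibits
SYN1326	unknown
SYN2178	unknown
SYN0692	unknown
SYN1215	unknown
SYN0799	induces
SYN0856	induces
SYN1743	induces
SYN1600	induces
SYN0174	induces
SYN0282	induces
GDF15	induces
SYN1630	induces
SYN2719	induces
SYN2875	induces
SYN2863	induces
SYN1494	induces
SYN0633	inhibits
LMNB1	inhibits
IL1B	induces
SYN2307	inhibits
SYN0976	induces
SYN2273	induces
NFKB1	induces
SYN2467	inhibits
SYN0456	unknown
SYN0449	induces
SYN1533	induces
SYN2813	induces
SYN2439	induces
SYN0290	inhibits
SYN2694	induces
SYN0361	induces
SYN2674	induces
SYN2471	inhibits
SYN0768	induces
SYN0958	induces
SYN2816	inhibits
SYN2494	inhibits
MMP3	induces
SYN2868	inhibits
SYN0246	induces
SYN2044	induces
SYN1652	induces
SYN1514	inhibits
SYN2516	induces
SYN2332	unknown
SYN2013	induces
SYN1281	inhibits
SYN0213	inhibits
SYN1774	induces
SYN0827	induces
SYN0483	induces
IGFBP3	induces
SYN2800	unknown
SYN2914	induces
SYN1719	inhibits
SYN1093	unknown
SYN1683	induces
SYN0421	induces
SYN2285	induces
SYN0325	induces
SYN2574	induces
SYN1301	inhibits
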