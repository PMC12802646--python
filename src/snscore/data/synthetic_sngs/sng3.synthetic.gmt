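SNG3	synthetic stand-in senescence gene set	TGFB1	SYN0125	SYN2093	SYN1605	SYN2660	SYN2836	SYN2510	SYN1732	SYN1995	SYN1862	CXCL8	SYN2173	SYN1973	SYN1776	SYN2197	SYN2260	SYN1295	SYN1595	SYN2152	SYN0557	SYN1572	SYN0140	SYN2350	SYN0395	SYN1155	SYN0062	SYN0142	TIMP2	SYN0888	SYN2079	SYN1381	SYN0266	SYN1345	SYN0748	SYN2879	SYN1002	SYN1302	SYN1331	SYN2376	SYN0017	SYN0776	CCNB1	SYN0334	SYN1886	SYN0453	SYN0959	SYN1965	SYN1203	SYN2895	SYN1761	SYN1191	SYN0743	SYN2334	SYN1937	SYN1038	SYN2069	STAT1	SYN0811	SYN2369	SYN2396	SYN1923	SYN0212	SYN2092	SYN0277	SYN0849	SYN2217	SYN0047	SYN2313	SYN2831	SYN2255	SYN0065	SYN0883	SYN0889	SYN1444	SYN2245	SYN0711	SYN2924	SYN2045	SYN0408	SYN2295	SYN0647	SYN0630	SYN0838	SYN2065	SYN2805	SYN1342	SYN0136	SYN0414	SYN1470	SYN0413	SYN2382	SYN2122	IGFBP7	SYN1182	SYN0570	SYN1777	SYN0980	SYN2549	SYN0425	SYN0535	IL6	SYN1650	SYN1700	SYN0209	SYN2073	SYN2823	SYN2788	SYN1911	SYN0321	SYN2444	SYN1683	SYN1251	SYN2750	SYN0080	SYN0553	SYN2817	SYN0275	SYN1809	ICAM1	SYN1686	SYN2804	SYN0550	SYN2140	SYN1418	SYN0148	SYN0821	SYN2134	SYN2178	SYN0974	SYN0579	SYN2665	SYN1125	SYN1176	SYN2837	SYN2410	SYN0761	SYN2014	SYN1521	SYN1276	SYN1635	SYN0155	SYN0976	SYN0876	SYN1190	CDK1	GLB1	SYN0530	SYN1505	SYN1104	SYN1119	SYN2194	SYN1785	SYN1036	SYN0609	SYN1222	SYN2126	SYN2609	SYN0511	SYN1884	SYN0259	SYN2678	SYN0532	SYN2036	SYN1395	SYN0804	SYN0491	SYN1577	SYN2862	SYN2421	SYN2018	SYN1384	SYN0906	SYN2486	SYN1441	SYN1771	SYN2344	SYN0374	SYN1243	SYN1731	SYN1955	SYN0383	SYN1462	SYN0983	SYN2264	SYN0538	SYN2413	SYN1113	SYN1986	SYN2053	SYN0700	SYN2398	SYN1474	SYN2207	SYN0083	SYN2684	SYN1607	SYN1720	SYN2509	SYN0602	SYN2529	SYN1429	SYN1849	SYN0222	SYN1460	SYN1410	CDKN2B	SYN1883	SYN0641	SYN1476	SYN0806	SYN2166	SYN2387	SYN2719	SYN1330	SYN1842	SYN1640	SYN0752	SYN1888	SYN1767	SYN0014	SYN1233	SYN1413	SYN2569	SYN1860	SYN0861	SYN1947	SYN2764	SYN0286	SYN2583	SYN1236	SYN0706	SYN2157	SYN0562	SYN1426	SYN1795	SYN1310	SYN0467	SYN0479	SYN1749	SYN1578	SYN2858	SYN2355	SYN2222	SYN1903	SYN2919	SYN1365	CCL2	SYN0564	SYN2336	SYN1844	SYN0798	SYN0970	SYN1948	SYN2650	SYN1136	SYN2487	SYN1054	SYN1684	SYN1477	SYN2499	CDKN1B	SYN1128	SYN0757	SYN0118	SYN0406	SYN2627	SYN0843	SYN2584	SYN2705	SYN0944	SYN2508	SYN0714	SYN2746	SYN1123	SYN2352	SYN0867	SYN1223	SYN2876	SYN1270	SYN1708	SYN1685	SYN0501	SYN0922	SYN2737	SYN0349	SYN2826	SYN1225	SYN0486	SYN2507	SYN1936	SYN1217	SYN0892	SYN1564	SYN1663	FOS	SYN2495	SYN1991	SYN0528	SYN1619	SYN2596	SYN0157	SYN2721	SYN2891	SYN1773	SYN0310	SYN2374	SYN1144	SYN0903	SYN0396	SYN0938	SERPINE2	SYN0820	SYN2713	SYN1192	SYN1456	SYN0745	SYN1719	SYN2516	CCL20	SYN1636	SYN0058	SYN1616	SYN1800	SYN1430	SYN1904	SYN0689	SYN2367	SYN0470	SYN2726	SYN2156	SYN0650	SYN2373	TP53	SYN2471	SYN1328	SYN0998	SYN2759	SYN2003	SYN2024	SYN1754	SYN2153	SYN1404	SYN0499	SYN0522	SYN2639	SYN1006	SYN2556	SYN0935	IGFBP3	B2M	SYN0305	SYN0899	SYN2889	SYN2277	SYN2229	SYN0378	SYN0693	CDKN1A	SYN2181	EZH2	SYN1422	SYN0521	SYN0344	SYN2055	SYN1327	SYN2179	SYN0707	SYN2343	SYN2279	SYN2385	SYN0824	SYN1671	SYN1504	SYN2578	SYN0628	SYN2340	SYN2873	SYN2268	SYN1126	SYN2007	SYN2009	SYN1423	SYN2477	SYN0873	SYN2907	JUN	SYN1020	SYN2184	SYN2270	SYN1701	SYN2794	SYN0019	SYN2845	SYN2695	SYN1256	SYN0088	SYN2262	SYN1337	SYN2668	SYN0606	SYN0238	SYN1659	SYN0690	SYN2485	SYN0649	SYN0415	SYN0805	SYN0255	IL1A	SYN0242	SYN1267	SYN1943	SYN1056	SYN0228	SYN1832	SYN0279	SYN0545	SYN1892	SYN1060	SYN2441	SYN2872	SYN1807	SYN1439	SYN0109	SYN2736	SYN1092	SYN2128	SYN0665	SYN0697	SYN0884	SYN0061	FAS	SYN0068	SYN1548	SYN2470	SYN0307	CXCL2	SYN0072	SYN1870	SYN2475	SYN1881	SYN0292	SYN2363	SYN0696	SYN1034	SYN0966	SYN2598	SYN2169	SYN2142	SYN2688	SYN2394	SYN2830	SYN2234	SYN1179	SYN2432	SYN1344	SYN1852	SYN2021	SYN0478	SYN0826	SYN2439	IGF1	SYN1592	SYN2776	SYN1278	SYN0296	SYN2330	SYN2395	SYN2265	SYN0919	SYN0734	SYN1096	SYN2221	SYN2218	SYN1177	SYN0880	SYN0146	SYN1829	SYN0411	SYN0671	SYN0253	SYN2770	SYN1899	SYN1932	SYN0357	SYN0946	SYN1916	SYN2286	SYN0389	SYN0508	SYN0948	SYN1343	SYN0986	SYN2638	SYN0167	SYN0863	SYN1801	SYN0455	SYN0457	SYN1913	SYN2306	SYN2099	SYN2599	SYN0780	SYN2890	SYN2043	SYN2840	SYN1311	SYN0030	SYN1996	SYN0273	SYN2554	SYN1676	SYN2645	SYN2581	SYN0859	SYN0403	SYN0236	TNFRSF10C	SYN2002	SYN1063	SYN0648	SYN0227	SYN2146	SYN2464	SYN1137	SYN1072	SYN1714	SYN2096	SYN2143	SYN1972	SYN1235	MKI67	SYN1908	SYN2354	SYN0325	SYN2315	SYN2161	SYN1219	SYN2711	SYN2356	SYN0449	SYN0853	SYN0377	SYN1857	SYN0943	SYN2215	SYN1388	SYN2843	SYN2278	SYN2472	SYN0599	SYN0024	SYN2515	SYN1743	CDKN2A
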