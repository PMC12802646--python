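SNG4	synthetic stand-in senescence gene set	SYN0113	SYN0179	SYN0677	FOS	SYN0438	SYN2224	IL6	SYN0358	SYN0759	SYN0357	SYN0789	SYN2479	SYN0270	SYN0924	SYN2531	SYN2202	SYN2214	SYN1398	SYN1250	SYN2831	SYN0526	SYN2312	SYN2597	SYN0090	SYN1713	SYN0048	SYN1091	SYN0330	SYN0464	SYN2042	SYN1510	SYN1390	SYN2102	SYN1000	SYN0069	SYN0386	SYN0269	IGFBP3	SYN1114	SYN0988	SYN0232	SYN1872	SYN2813	SYN0630	SYN1776	SYN2323	SYN2050	SYN2251	SYN0713	SYN2402	SYN0736	SYN1379	SYN0745	IL1B	SYN1796	SYN1666	SYN0805	SYN1979	SYN1036	SYN0628	CDKN2A	SYN1156	SYN2912	SYN2308	SYN2052	SYN0716	SYN0857	SYN1569	SYN0110	SYN2583	SYN2211	SYN1591	SYN1249	TGFB1	SYN0388	SYN1794	MMP3	SYN1134	IGFBP5	SYN2487	IGFBP7	SYN0952	SYN2289	GLB1	SYN0405	SYN1267	SYN1384	SYN0639	SYN0319	SYN2062	SYN1683	SYN0724	SYN2109	SYN2207	SYN2269	SYN1523	SYN0796	STAT1	SYN1688	SYN2913	SYN2712	SYN0916	SYN1302	SYN0293	SYN0962	SYN0792	SYN1046	SYN2041	SYN2112	SYN1617	SYN2652	NFKB1	IGF1	SYN0892	SYN2029	SYN2613	SYN0398	SYN2006	SYN0573	SYN2051	SYN0327	SYN2767	SYN2760	SYN0588	SYN0984	SYN1413	SYN2352	SYN1099	SYN1943	SYN2025	SYN1924	SYN0261	SYN2181	SYN0565	SYN0837	SYN1028	SYN2483	SYN2549	SYN1712	SYN0368	SYN2833	SYN0423	MMP1	SYN2770	SYN0991	SYN0915	SYN0391	SYN0033	SYN0272	SYN2925	SYN1013	SYN0872	SYN2826	SYN0483	SYN0847	SYN2460	SYN1264	SYN0177	SYN0104	SYN2264	SYN0154	SYN1974	SYN1505	SYN0217	SYN1741	SYN1710	SYN2571	SYN0911	SYN2493	SYN2744	SYN2866	SYN2927	SYN2072	SYN1962	SYN1166	SYN2874	SYN1002	SYN2688	SYN1073	CCNB1	SYN2279	SYN0793	SYN1956	SYN2648	SYN2364	SYN1740	SYN1758	GDF15	SYN0732	SYN2683	CDKN1B	SYN0336	SYN1692	SYN2322	SYN2691	SYN0326	SYN0861	SYN2713	SYN0013	SYN2518	SYN1495	SYN1490	SYN0095	SYN0618	SYN0204	SYN2774	SYN2696	SYN0665	SYN1207	SYN2188	SYN1778	SYN1435	SYN0967	SYN1354	SYN2100	SYN2367	SYN0550	SYN0688	SYN2383	SYN2073	SYN0775	SYN0361	SYN2603	SYN0663	SYN1424	SYN1772	SYN1183	IL1A	SYN2899	SERPINE2	SYN0212	SYN2419	TNFRSF10C	SYN0518	SYN0475	SYN2240	SYN1402	SYN0632	SYN1827	SYN2697	SYN0093	SYN0030	SYN0130	CCL2	SYN1199	SYN2456	SYN2769	CDKN2B	SYN0160	SYN2020	SYN0428	SYN0178	EZH2	SYN1304	SYN0036	SYN1647	SYN1574	SYN0351	SYN0253	SYN1221	SYN2660	SYN1792	SYN0885	SYN1782	SYN1016	SYN2604	TIMP2	SYN2420	SYN2234	SYN0765	CXCL8	SYN2686	SYN1941	SYN1106	SYN1761	SYN0156	SYN1783	SYN0919	SYN2564	SYN1701	CCL20	SYN0383	SYN0681	SYN0411	SYN2343	SYN0599	SYN0808	SYN0404	SYN0060	SYN2384	SYN2189	SYN1540	SYN0839	SYN2557	SYN2183	SYN1876	SYN1915	SYN2482	B2M	SYN2003	SYN0097	TP53	SYN0010	SYN1310	SYN2028	SYN0912	SYN2578	SYN1791	SYN1527	SYN1418	SYN1645	SYN2888	SYN1684	SYN2449	SYN1816	SYN1477	SYN2369	SYN1636	SYN1637	SYN0143	SYN0265	SYN0273	SYN1032	SYN0672	SYN2468	SYN1331	SYN1419	SYN1922	SYN0653	SYN1858	SYN2040	SYN0948	SYN0690	SYN1043	SYN1260	SYN1332	SYN0819	SYN1882	SYN1655	SYN2314	SYN0832	SYN1546	SYN1187	SYN0852	SYN2300	SYN0443	SYN2875	SYN2628	SYN1851	SYN2858	SYN1337	SERPINE1	SYN0926	SYN0492	SYN1897	SYN0452	SYN2563	SYN2341	SYN0065	SYN1165	SYN1276	SYN1319	SYN1978	SYN1779	SYN0561	SYN1093	MKI67	SYN1577	SYN2200	SYN2302	SYN1334	SYN0929	SYN1170	SYN2445	SYN2201	SYN0851	SYN0276	SYN2295	SYN1371	SYN2395	SYN0801	SYN2159	SYN2768	SYN2033	SYN1180	SYN0436	SYN0899	SYN2753	SYN0624	SYN1729	SYN2117	SYN0354	SYN0687	SYN2609	SYN0376	SYN0890	SYN2735	SYN0721	LMNB1	SYN1233	SYN2800	SYN2242	SYN2318	SYN2568	SYN0562	SYN1620	SYN1877	SYN1954	SYN2864	SYN0836	SYN1998	SYN2592	SYN0950	SYN0426	SYN2601	SYN0396	SYN0374	SYN2903	SYN1122	SYN2618	SYN1780	SYN1525	SYN0484	SYN1838	SYN2239	SYN1063	SYN0891	SYN2590	SYN0969	SYN1439	SYN0581	SYN0413	SYN1006	SYN0435	SYN2491	SYN0580	SYN1967	SYN0414	SYN0525	SYN1594	SYN1173	SYN2127	SYN0139	SYN1397	SYN0159	SYN1141	SYN0741	SYN1675	SYN1214	SYN1303	SYN0056	SYN0171	SYN1804	TIMP1	SYN1001	SYN2885	SYN1745	SYN1406	SYN0514	SYN0236	SYN2256	SYN0331	SYN2262	SYN1702	SYN2610	SYN2291	SYN1625
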