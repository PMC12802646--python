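SNG2	synthetic stand-in senescence gene set	SYN2679	SYN0614	SYN1807	TIMP1	SYN0405	SYN1860	SYN2059	SYN0602	SYN2722	SYN1203	SYN2285	SYN1590	SYN2348	SYN2564	SYN2223	SYN0764	SYN0359	SYN1443	SYN0623	SYN0684	SYN0737	SYN1260	SYN2490	SYN2776	SYN2314	SYN1088	SYN0636	SYN0541	SYN2772	SYN1489	SYN0972	SYN2185	SYN1413	SYN1467	SYN2339	SYN0968	SYN2137	SYN2423	SYN1549	SYN0285	SYN2011	SYN1970	SYN1804	SYN0849	SYN2090	SYN0574	SYN1597	SYN0415	SYN0883	SYN0641	SYN0238	SYN0017	SYN0172	SYN0775	SYN1899	MMP3	SYN1365	SYN0822	SYN2716	SYN0707	SYN1154	SYN0805	TIMP2	SYN1693	SYN2328	SYN0742	SYN1084	SYN2399	SYN0045	SYN0568	SYN0381	SYN2896	CXCL2	SYN0694	SYN2293	SYN2573	SYN0987	SYN0089	SYN2901	SYN0691	SYN0616	SYN2860	SYN2481	SYN2630	SYN1363	SYN0795	SYN2098	SYN2602	SYN1392	SYN2889	SYN0444	SYN0865	SYN0199	SYN1301	SYN2616	SYN1799	SYN1865	SYN0980	SYN1109	SYN1378	SYN0503	SYN2519	SYN0481	SYN0114	SYN1495	SYN0025	SYN2739	SYN0697	SYN2870	SYN1405	SYN2367	SYN2000	SYN1143	SYN1900	SYN1667	SYN1292	SYN0153	SYN2351	SYN0583	SYN2115	SYN0035	SYN2790	SYN0627	SYN2585	TGFB1	SYN1487	CDKN1A	SYN0955	SYN2825	SYN1734	SYN0348	SYN2279	SYN0654	CXCL1	SYN1445	SYN2324	SYN1300	SYN2890	IL1A	SYN1386	SYN0721	SYN2674	SYN1290	SYN0971	SYN1754	SYN0455	SYN1093	SYN1530	SYN2231	SYN0745	SYN0577	SYN0844	SYN1925	SYN0002	SYN0551	SYN1739	SYN1756	SYN0978	SYN1320	SYN2693	SYN0966	SYN1011	SYN1297	SYN1307	SYN0925	SYN1430	SYN1427	SYN0263	SYN2289	SYN2451	SYN0164	SYN2038	SYN2795	LMNB1	SYN2186	SYN2902	SYN0292	CDKN2A	TNFRSF10C	SYN2487	SYN1575	SYN2879	SYN2592	SYN2643	SYN0304	SYN0469	SYN2501	SYN2407	SYN2030	SYN0183	SYN1168	SYN0617	SYN0203	SYN0312	SYN0639	SYN1138	SYN2113	SYN1454	SYN1316	SYN0915	SYN2458	SYN1481	SYN2861	SYN1067	SYN0340	SYN2374	SYN2086	SYN0787	SYN1889	SYN0357	SYN1786	GLB1	SYN1024	SYN0665	SYN1420	SYN2914	SYN2120	SYN0341	SYN0560	SYN0590	SYN2170	SYN2660	SYN2396	SYN0575	SYN0947	SYN0178	SYN1984	SYN1663	SYN2435	SYN1924	SYN0109	SYN0683	SYN2203	SYN2087	SYN0959	SYN2433	SYN0380	SYN2912	GDF15	SYN2658	SYN1568	SYN2712	SYN2898	SYN0368	SYN1479	SYN0449	SYN0682	SYN0586	SYN1543	SYN2578	SYN2775	SYN0234	SYN1480	SYN2393	SYN2389	SYN2748	SYN1302	SYN2016	SYN0931	SYN0394	SYN0772	SYN1426	SYN2454	SYN0093	SYN2683	SYN2136	SYN2534	SYN0268	SYN1653	SYN0573	SYN0923	SYN2514	SYN0760	SYN1053	SYN1826	SYN2580	SYN2166	SYN2631	SYN1722	SYN0170	SYN2715	SYN1731	SYN0812	SYN1976	SYN2377	SYN0137	SYN0154	SYN0072	SYN0729	SYN0838	SYN0212	SYN2847	SYN1645	SYN1691	SYN2508	SYN2359	SYN0869	NFKB1	SYN2360	CCL20	SYN1662	SYN1736	SYN1805	SYN0510	SYN2461	SYN0997	SYN1806	SYN0254	SYN2018	SYN0845	SYN0117	SYN0079	SYN1783	SYN2541	SYN1661	SYN1540	SYN0461	SYN0939	SYN0426	SYN1171	SYN0531	SYN0719	SYN0791	SYN1674	SYN2091	SYN1601	SYN0335	SYN1993	SYN1513	SYN2608	SYN1453	SYN1528	SYN0543	SYN2768	SYN1703	IGF1	SYN1349	IL1B	SYN0302	SYN1852	SYN1515	SYN2472	SYN1359	SYN2409	SYN0640	SYN1777	SYN0145	SYN0362	SYN0912	SYN1752	SYN0176	SYN0086	SYN1401	SYN1603	SYN0989	SYN1613	SYN1458	SYN1894	SYN1559	SYN0039	SYN1436	SYN2767	SYN0862	SYN2337	SYN1946	SYN1230	SYN2023	SYN2085	SYN2460	SYN2411	SYN2301	SYN0023	SYN2859	SYN1408	SYN1492	SYN0629	SYN2685	SYN2258	SYN2229	SYN2761	SYN1514	SYN0860	SYN2017	SYN1585	ICAM1	SYN0809	SYN0020	SYN0171	SYN0720	SYN2486	SYN0129	SYN2373	SYN1146	SYN0253	SYN2788	SYN0198	SYN1135	MKI67	SYN1141	SYN1397	SYN0495	SYN0326	SYN1263	SYN1491	SYN2848	SYN2711	SYN0428	SYN0480	SYN1484	SYN1506	SYN1915	SYN2092	SYN2849	SYN2029	SYN0488	SYN0815	SYN2058	SYN1014	SYN0477	SYN0942	SYN0841	SYN2742	SYN1547	SYN1529	SYN1533	SYN0430	SYN0723	IGFBP5	SYN2189	SYN1237	SYN0442	SYN2811	SYN1747	SYN1840	SYN0225	SYN1423	SYN0228	CDKN2B	SYN1251	SYN1367	SYN2145	SYN0277	SYN2471	SYN2496	SYN1066	SYN1280	SYN1502	SYN1913	SYN0006	SYN2905	SYN1226	SYN2654	SYN1843	SYN1294	SYN0497	SYN1811	SYN1465	SYN0747	SYN1612	SYN1763	SYN1950	SYN0155	SYN0901	SYN2728	SYN0463	SYN0222	SYN0046	SYN0206	SYN2646	SYN0291	SYN0215	SYN0174	SYN1438	SYN1638	SYN0083	SYN1845	SYN0396	SYN2741	SYN1973	SYN2642	SYN1886	SYN2667	CCL2	SYN0429	SYN0456	SYN2278	SYN0730	SYN2259	SYN2636	SYN1916	SYN1122	SYN1797	SYN2386	SYN0128	SYN2039	SYN1353	SYN2390	SYN2506	SYN2250	SYN1828	SYN1609	SYN1699	SYN1460	SYN0032	SYN0042	SYN0527	SYN1278	SYN0678	SYN0475	SYN0055	SYN1727	SYN0552	SYN1864	SYN0338	SYN2449	SYN1318	IGFBP7	SYN0516	SYN2232	SYN1440	SYN2709	SYN2836	SYN2917	SYN2782	SYN0473	SYN1822	SYN1043	SYN0700	SYN1219	SYN1892	SYN2865	CCNB1	SYN1628	SYN1963	SYN1573	SYN2421	SYN2130	SYN0555	SYN1121	SYN2464	SYN0920	SYN1994	SYN2160	SYN2462	SYN0257	SYN2758	SYN1784	SYN2921	SYN1650	SYN2369	FOS	STAT1	SYN2571	SYN0247	SYN2522	SYN2467	SYN1582	SYN2209	SYN1490	SYN0774	SYN2465	SYN1485	SYN0895	SYN2338	SYN0364	SYN2272	SYN2778	SYN0751	SYN1070	SYN2405	SYN2600	SYN2611	SYN1097	SYN0207	SYN0854	SYN1131	SYN2267	SYN2705	SYN2064	SYN2233	SYN1748	SYN1394	SYN0436	SYN0949	SYN2545	SYN2894	SYN2725	SYN0716	SYN0298	JUN	SYN1610	SYN1586	SYN2634	SYN1334	SYN1566	SYN2196	SYN1769	SYN0101	SYN2443	SYN2060	SYN1252	SYN0975	SYN1696	SYN0427	SYN2731	SYN2770	TP53	SYN0562	SYN1404	SYN1169	SYN1718	SYN0801	SYN1912	SYN1738	SYN2581	SYN1873	SYN0847	SYN0287	SYN0375	SYN2019	SYN1262	SYN2131	SYN1733	SYN0735	SYN1396	SYN2183	SYN0420	SYN2325	SYN1466	SYN0141	SYN1459	SYN2106	SYN1698	SYN2261	SYN2687	SYN0806	SYN2852	SYN1247	SYN0746	SYN1724	CDK1	SYN1192	SYN1107	EZH2	SYN0323	SYN0356	SYN0726	SYN2546	SYN1162	SYN1140	SYN2533	SYN0664	SYN1127	SYN2358	SYN2826	SYN1052	SYN0810	SYN0717	SYN1083	SYN1044	SYN2543	SYN1002	SYN0059	SYN1883	SYN2675	SYN0710	SYN2049	SYN0769	SYN1593	SYN1199	SYN0088	SYN0328	SYN2103	SYN0898	SYN0852	SYN1218	SYN1288	SYN0892	SYN1842	SYN2321	SYN0524	SYN1641	SYN0324	SYN1909	SYN2329	SYN1732	SYN0360	SYN0073	SYN1871	SYN1553	SYN1651	SYN0076	SYN2327	SYN1914	SYN2249	SYN2168	SYN0603	SYN2647	SYN2070	SYN1055	SYN1144	SYN2215	SYN1712	SYN2275	SERPINE1	SYN0233	SYN1124	SYN0182	SYN0918	SYN1115	SYN1324	SYN0523	SYN1344	SYN2295	SYN2414	SYN2554	SYN2621	SYN2789	SYN0943	SYN0084	SYN2518	SYN1289	SYN0081	SYN1112	SYN2043	SYN0148	SYN1567	SYN2762	SYN1587	SYN2083	SYN1179	SYN2073	SYN1269	SYN2798	SYN2345	SYN2392	SYN1621	SYN2224	SYN2601	SYN0308	SYN1174	SYN0236	SYN2641	SYN1905	SYN0049	B2M	SYN2699	SYN0016	SYN1812	SYN0448	SYN0208	SYN0621	SYN2132	SYN1584	SYN2296	SYN0579	SYN2547	SYN0030	SYN1829	SYN0407	SYN2668	SYN0902	SYN1673	SYN2225	SYN2574	SYN2584	SYN2254	SYN1719	SYN0593	SYN2485	SYN0965	SYN0843	SYN2586	SYN1068	SYN2426	SYN0519	SYN2079	SYN0658	SYN1118	SYN1475	SYN2046	SYN0393	SYN0893	SYN1720	SYN0571	SYN2380	SYN1184	SYN0798	SYN1415	SYN2056	SYN0928	SYN0662	SYN2174	SYN0786	SYN0570	SYN0125	SYN0343	SYN2268	SYN0249	SYN1239	SYN0184	SYN2266	SYN2157	SYN2532	SYN0508	SYN1193	MMP1	SYN1660	SYN1200	SYN2521	SYN0311	SYN2892	SYN0680	SYN1798	SYN1104	SYN2095	SYN1675	SYN2089	SYN0498	SYN2104	SYN1100	SYN0921	SYN1008	SYN1414	SYN2595	SYN2281	SYN2356	SYN1801	IL6	SYN1221	SYN1206	SYN0443	SYN0934	SYN2299	SYN1751	SYN2489	SYN2834	SYN2818	SYN1337	SYN0624	SYN1142	SYN0445	SYN2598	SYN1670	SYN2785	SYN0066	SYN0872	SYN2727	SYN2707	SYN1817	SYN0777	SYN0783	SYN1007
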