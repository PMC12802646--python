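SNG5	synthetic stand-in senescence gene set	IGFBP3	SYN1076	SYN0915	SYN1159	SYN2144	SYN0919	SYN1321	SYN1189	SYN2801	SYN0675	SYN1626	SYN2043	SYN2524	SYN0816	SYN2239	SYN2309	SYN0187	SYN2132	SYN2164	SYN0223	SYN0188	FOS	SYN1624	SYN0724	SYN0932	SYN1613	EZH2	SYN2718	SYN1344	SYN2757	SYN0130	SYN2767	SYN0571	SYN1236	SYN2720	SYN0773	SYN2148	SYN0158	SYN0981	SYN0410	SYN0766	SYN0831	SYN0683	SYN0507	SYN0048	CCL2	SYN2823	SYN2123	SYN2725	IGFBP5	SYN0182	SYN0472	CCL20	SYN1331	SYN0770	SYN2439	SYN2190	SYN2206	SYN2165	SYN0673	SYN2471	SYN0942	SYN1906	SYN2255	SYN2372	SERPINE1	SYN0703	SYN1291	SYN0625	SYN1056	SYN0681	SYN2078	SYN1356	SYN0642	SYN1756	SYN0297	SYN2710	SYN1433	SYN0730	SYN0552	SYN0570	SYN2871	SYN1242	SYN1153	SYN0534	SYN2555	SYN2158	CDKN1A	SYN2678	SYN0828	SYN0221	SYN0468	SYN2222	SYN1837	SYN1514	SYN0466	SYN0572	SYN1880	SYN0862	SYN2246	SYN1255	SYN1413	SYN0308	SYN2135	SYN1958	SYN0631	CXCL8	SYN2403	SYN1314	SYN1392	SYN1591	SYN2527	SYN1066	SYN0823	SYN0790	SYN0900	SYN1271	SYN1104	SYN0034	SYN2213	SYN0615	SYN2073	SYN0162	GLB1	SYN0111	SYN1133	SYN1308	SYN1253	SYN2089	SYN2012	SYN1277	SYN0463	SYN0853	SYN1824	SYN1357	SYN1597	SYN1378	SYN1021	SYN0123	SYN1600	SYN0222	SYN1602	SYN0548	SYN2641	SYN1110	SYN1232	SYN2724	SYN1387	SYN1892	SYN2884	SYN2792	SYN0146	SYN1885	SYN2762	SYN2584	SYN1305	SYN1085	SYN0372	JUN	SYN2466	SYN2729	SYN0869	SYN0412	SYN1283	SYN1350	SYN2617	SYN1903	SYN1497	SYN1161	SYN0860	SYN0909	SYN0213	SYN1541	SYN2393	SYN0329	SYN0166	SYN1951	SYN1286	SYN0872	SYN2864	SYN1814	SYN1201	SYN2612	SYN1526	SYN1385	SYN1446	SYN0112	SYN1301	SYN0205	SYN1228	SYN0561	SYN1558	SYN1818	SYN0047	SYN0873	SYN1681	SYN0021	SYN0489	SYN1089	SYN1205	SYN2453	SYN0660	SYN0435	SYN1120	SYN2412	SYN1248	SYN0294	SYN0943	SYN0192	SYN2306	SYN2097	SYN2663	SYN0878	SYN1355	SYN1384	SYN2614	SYN1211	SYN0780	SYN0269	SYN0363	SYN1900	SYN1230	SYN1898	SYN0566	SYN0520	SYN2768	SYN1102	SYN1609	SYN2615	SYN2419	SYN2049	SYN0621	SYN0707	SYN1593	SYN1598	SYN0105	GDF15	SYN0963	TIMP1	SYN1533	SYN0226	SYN2856	SYN1274	SYN0164	SYN0003	SYN1260	SYN1160	SYN1628	SYN1348	SYN0310	SYN0471	SYN1498	SYN1679	SYN2568	SYN0499	SYN2780	MKI67	SYN0619	SYN1557	SYN0461	TP53	TNFRSF10C	SYN1448	SYN2763	SYN2319	SYN1546	SYN1306	SYN2588	SYN1317	TGFB1	CDKN1B	SYN0354	SYN1393	SYN2029	SYN1324	SYN0488	SYN0077	SYN1991	SYN1129	SYN0220	SYN0877	SYN1949	SYN1341	SYN2914	SYN1522	SYN0189	SYN1202	SYN1090	SYN2552	SYN0165	SYN0843	SYN0854	SYN0129	SYN2262	STAT1	SYN2167	SYN1072	SYN0281	SYN2335	SYN1146	SYN2389	SYN2532	LMNB1	SYN1403	SYN0278	SYN2326	SYN1036	SYN1101	SYN1483	SYN1871	SYN1040	SYN0567	SYN1506	SYN0024	SYN2080	SYN2333	SERPINE2	SYN1848	SYN0914	SYN1787	SYN1589	SYN2027	SYN0546	SYN1565	SYN0655	SYN0487	SYN1406	MMP3	SYN1127	SYN0647	SYN2649	SYN0288	SYN2528	SYN0434	SYN2537	SYN2452	SYN1642	SYN2366	SYN1411	SYN1280	SYN0054	B2M	SYN2554	SYN0064	SYN1082	SYN1769	SYN1672	SYN1078	SYN1361	SYN1035	SYN2162	IL1A	SYN2257	SYN0941	SYN1856	SYN0699	SYN1857	SYN0608	SYN1983	SYN1532	SYN1968	SYN1423	SYN1269	SYN0512	SYN0555	SYN1618	SYN2283	SYN2180	SYN2110	SYN1744	SYN1214	SYN2057	SYN2187	SYN2832	SYN2082	CCNB1	SYN2880	SYN2714	IL6	SYN2746	SYN2523	SYN1800	SYN2594	SYN1648	SYN1282	SYN0346
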