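SNG6	synthetic stand-in senescence gene set	SYN2329	SYN0392	SYN0220	SYN0194	SYN2172	SYN1202	SYN1392	SYN1117	SYN1825	SYN1650	SYN0862	SYN2666	SYN2299	TP53	SYN2177	SYN2327	SYN0218	SYN2261	SYN2526	SYN0156	SYN0244	SYN0610	SYN1377	SYN2114	SYN0879	SYN1787	SYN1094	SYN1781	SYN2425	SYN1198	SYN2203	SYN1146	SYN2304	SYN0727	SYN2157	SYN1553	SYN0701	SYN2414	SYN2154	SYN2390	SYN0128	SYN2339	SYN0158	SYN0116	SYN1050	SYN0942	SYN0995	SYN1730	SYN2200	SYN0436	SYN0193	SYN0098	SYN1465	SYN0411	SYN1981	SYN2236	SYN1883	SYN2076	EZH2	SYN0354	SYN1649	SYN2135	SYN1719	SYN1777	SYN1770	SYN2406	SYN2008	SYN2743	SYN0647	CDK1	SYN2797	SYN0131	IL1B	SYN2311	SYN2581	SYN1499	SYN0420	SYN2800	SYN2178	SYN0026	SYN2054	SYN2755	SYN2511	SYN0813	SYN1892	SYN2682	SYN1678	SYN1746	SYN2456	SYN2829	SYN1164	SYN0704	SYN1147	SYN2193	SYN2244	SYN0031	SYN1333	SYN1525	SYN0685	SYN2751	SYN0608	SYN0219	SYN2185	SYN2560	SYN2293	SYN1066	SYN1813	NFKB1	SYN1029	SYN2674	SYN2484	SYN2176	SYN1226	SYN1075	SYN1141	SYN2756	SYN1394	SYN2634	SYN2190	SYN1325	SYN1654	SYN1669	SYN0240	SYN0806	SYN0425	SYN0597	SYN1975	SYN0383	SYN2865	SYN0917	FAS	SYN1018	SYN1095	SYN2268	SYN1651	SYN1926	SYN2879	SYN1079	IGFBP5	SYN0782	SYN2211	SYN0362	TNFRSF10C	SYN2701	JUN	SYN0677	SYN1163	SYN1630	SYN2915	SYN1501	SYN0510	SYN2249	SYN1664	SYN0351	SYN1456	SYN1547	SYN2276	SYN2593	SYN0012	SYN1399	SYN2198	SYN0753	SYN0673	SYN1096	SYN2649	SYN1604	SYN0483	SYN2845	SYN0508	SYN0422	SYN0898	SYN1111	SYN0402	GLB1	SYN2265	SYN0300	SYN2216	SYN0239	SYN2449	SYN0492	SYN1033	SYN0256	CDKN1A	SYN0999	SYN0662	SYN1579	SYN1966	SYN2704	SYN2592	SYN0709	SYN2416	SYN1348	SYN2091	SYN1775	SYN0729	SYN0197	SYN1728	SYN0152	SYN1458	SYN1757	CXCL1	SYN2771	SYN0723	SYN1818	SYN2808	SYN1853	SYN2641	SYN2809	SYN2827	SYN0306	SYN1307	SYN1301	GDF15	SYN0798	SYN2661	SYN0951	SYN0412	SYN2356	SYN0997	SYN0878	SYN0708	SYN0607	SYN0488	SYN0337	SYN0910	SYN2127	SYN1909	SYN1300	SYN2509	SYN0554	SYN1338	SYN2495	SYN1268	SYN0552	SYN0913	SYN2822	SYN1373	ICAM1	SYN2035	SYN0096	SYN2005	SYN1208	SYN1192	SYN2463	SYN0935	SYN1622	SYN0108	SYN2167	CCL2	SYN0109	SYN2806	SYN2530	SYN0582	SYN1310	SYN2422	SYN0355	SYN1739	SYN1407	SYN1490	SYN1286	SYN0682	SYN2227	SYN1962	SYN1447	SYN0845	SYN2133	SYN1563	SYN0397	SYN2647	SYN1495	SYN0912	SYN1216	SYN0716	SYN1090	SYN0081	SYN1369	SYN1209	SERPINE2	SYN0538	SYN2207	SYN1868	SYN2004	SYN1951	FOS	SYN0168	SYN2362	SYN2524	SYN2907	IGFBP7	SYN0336	SYN2740	SYN1039	SYN2440	SYN1436	SYN2282	CDKN1B	SYN0886	SYN0961	SYN1984	SYN1471	SYN1538
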