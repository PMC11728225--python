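Locus	Na	Ne	I	Ho	He	PIC
G33	8	2.926	1.326	0.654	0.658	0.6103
G111	10	2.508	1.380	0.623	0.601	0.5758
G216	7	2.748	1.251	0.736	0.636	0.5793
G304	6	2.379	1.041	0.632	0.580	0.5108
G386	4	3.009	1.195	0.749	0.668	0.6055
G440	4	2.669	1.039	0.649	0.625	0.5464
G573	8	2.639	1.314	0.606	0.621	0.5911
G584	7	2.794	1.236	0.628	0.642	0.5879
G589	5	2.749	1.154	0.641	0.636	0.5660
G676	7	3.560	1.476	0.784	0.719	0.6811
G744	10	3.860	1.556	0.844	0.741	0.7001
G824	8	2.336	1.071	0.710	0.572	0.5138
G833	8	2.517	1.133	0.571	0.603	0.5463
G886	6	2.831	1.311	0.619	0.647	0.6093
G1028	8	4.277	1.563	0.409	0.766	0.7284
G1077	9	3.424	1.510	0.688	0.708	0.6705
G1097	8	4.075	1.500	0.823	0.755	0.7114
G1134	6	3.351	1.335	0.740	0.702	0.6481
G1151	5	3.646	1.366	0.823	0.726	0.6766
G1212	4	3.294	1.262	0.684	0.696	0.6390
G1234	5	3.015	1.315	0.857	0.668	0.6280
G1268	3	2.380	0.967	0.658	0.580	0.5085
G1342	5	3.022	1.211	0.758	0.669	0.6063
G1352	5	3.264	1.254	0.489	0.694	0.6313
G1360	5	3.466	1.339	0.931	0.711	0.6565
G1382	6	4.736	1.632	0.874	0.789	0.7569
G1424	9	3.952	1.541	0.771	0.747	0.7073
G1450	7	2.554	1.205	0.615	0.609	0.5596
G1454	7	4.664	1.652	0.771	0.786	0.7534
G1527	6	3.018	1.233	0.749	0.669	0.6050
G1617	5	2.763	1.161	0.589	0.638	0.5734
G1666	6	3.189	1.280	0.797	0.686	0.6298
G1745	6	3.454	1.345	0.827	0.710	0.6588
G1783	6	2.472	1.077	0.727	0.596	0.5159
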