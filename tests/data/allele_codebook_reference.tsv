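locus	1	2	3	4	5	6	7	8	9	A
G676	178	185	191	197	203	209	222
G744	139	142	145	154	162	165	168	174	177	180
G1028	99	102	105	111	114	117	120	129
G1077	119	122	125	128	131	134	137	140	145
G1097	131	134	138	142	145	151	154	157
G1134	106	112	119	126	133	139
G1151	194	197	200	203	206
G1212	135	138	141	149
G1234	87	93	99	105	111
G1352	130	133	137	144	147
G1360	123	126	129	132	135
G1382	104	107	110	113	116	119
G1424	88	91	97	100	103	106	109	112	124
G1454	119	122	125	128	131	134	137
G1666	110	113	116	119	122	125
G1745	118	121	124	127	130	133
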