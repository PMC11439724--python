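	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
A	0	111	110	126	195	91	107	60	85	94	96	106	84	113	27	99	58	148	112	64
R	111	0	85	96	180	43	54	125	29	98	102	26	92	97	103	109	71	101	77	96
N	110	85	0	23	139	46	41	79	68	149	152	94	141	158	90	46	65	174	142	133
D	126	96	23	0	154	61	45	94	81	168	172	101	160	177	108	65	85	191	160	152
C	195	180	139	154	0	154	169	158	174	197	197	202	196	204	169	112	149	214	194	191
Q	91	43	46	61	154	0	29	87	24	109	112	53	101	116	75	68	41	130	99	96
E	107	54	41	45	169	29	0	98	41	134	138	57	126	140	94	80	66	152	123	121
G	60	125	79	94	158	87	98	0	98	135	138	126	127	153	42	55	59	184	147	109
H	85	29	68	81	174	24	41	98	0	94	99	32	86	100	76	89	47	115	83	84
I	94	98	149	168	197	109	134	135	94	0	5	102	10	21	95	142	89	61	33	30
L	96	102	152	172	197	112	138	138	99	5	0	106	14	22	98	144	92	61	36	32
K	106	26	94	101	202	53	57	126	32	102	106	0	94	102	103	121	78	109	85	97
M	84	92	141	160	196	101	126	127	86	10	14	94	0	29	87	135	81	67	35	22
F	113	97	158	177	204	116	140	153	100	21	22	102	29	0	114	155	103	40	22	50
P	27	103	90	108	169	75	94	42	76	95	98	103	87	114	0	73	38	147	110	68
S	99	109	46	65	112	68	80	55	89	142	144	121	135	155	73	0	58	177	143	123
T	58	71	65	85	149	41	66	59	47	89	92	78	81	103	38	58	0	128	92	69
W	148	101	174	191	214	130	152	184	115	61	61	109	67	40	147	177	128	0	37	88
Y	112	77	142	160	194	99	123	147	83	33	36	85	35	22	110	143	92	37	0	55
V	64	96	133	152	191	96	121	109	84	30	32	97	22	50	68	123	69	88	55	0
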