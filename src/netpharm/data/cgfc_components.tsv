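component_id	name	mw	hdon	hacc	rbn	logp	ob
CHSGS2	quercetin	302.24	5	7	1	1.07	46.43
CHSGS3	4-Hydroxybenzoic acid	138.12	2	3	1	1.58	30.15
CHSGS4	vanillic acid	168.15	2	4	2	1.7	35.47
CHSGS5	Nonanal	142.24	0	1	7	3.81	40.28
CHSGS11	benzoic acid	122.12	0	2	1	1.72	31.55
CHSGS13	Jaranol	314.29	2	6	3	2.8	50.83
CHSGS17	isorhamnetin	316.26	4	7	2	1.31	49.6
CHSGS18	formononetin	268.26	1	4	2	3.01	69.67
CHSGS19	Calycosin	284.26	2	5	2	2.82	47.75
CHSGS20	kaempferol	286.24	4	6	1	1.23	41.88
CHSGS26	vanillin	152.15	1	3	2	1.31	52
CHSGS51	Polyhydric alcohols	92.09	3	3	2	-1.93	72.87
CHSGS52	Indole-3-carboxylic acid	161.16	2	2	1	1.79	33.86
CHSGS54	adenine	135.13	3	4	0	-0.38	62.81
CHSGS56	salicylic acid	138.12	2	3	1	1.96	32.13
CHSGS60	Dibutylphenol	206.32	1	1	2	4.9	38.9
CHSGS63	Methylgallate	184.15	3	5	2	1.01	30.91
CHSGS67	albiflorin_qt	318.32	2	6	4	0.53	66.64
CHSGS68	(3R,3aR,6S,7aR)-6-hydroxy-3,6-dimethyl-3a,4,7,7a-tetrahydro-3H-benzofuran-2,5-dione	198.22	1	4	0	0.02	104.94
CHSGS76	scoparone	206.19	0	4	2	1.91	74.75
CHSGS78	hexanoic acid	116.16	1	2	4	1.88	73.08
CHSGS79	Isovanillic acid	168.15	2	4	2	1.81	39.42
CHSGS81	Valerophenone	162.23	0	1	4	2.94	42.58
CHSGS82	Isobutyrophenone	148.2	0	1	2	2.54	80.37
CHSGS85	Perlolyrine	264.28	2	3	2	2.66	65.95
CHSGS86	senkyunolide-C	204.22	1	3	2	3.49	46.8
CHSGS87	senkyunolide-E	204.22	1	3	2	1.93	34.4
CHSGS89	1-Acetyl-beta-carboline	210.23	1	2	1	2.53	67.12
CHSGS93	WLN: 2VR	134.18	0	1	2	2.15	60.17
CHSGS96	3-cyclohexen-1-ol	98.14	1	1	0	0.96	70.57
CHSGS97	4,7-Dihydroxy-3-butylphthalide	222.24	2	4	3	2.69	106.09
CHSGS109	Apocynin	166.17	1	3	2	1.62	31.71
CHSGS114	Chryseriol	300.26	3	6	2	2.53	35.85
CHSGS116	m-Methylacetophenone	134.18	0	1	1	2.08	40.63
CHSGS118	Lupiwighteone	338.35	3	5	3	3.23	51.64
CHSGS119	7-Methoxy-2-methyl isoflavone	266.29	0	3	2	3.48	42.56
CHSGS121	Visnagin	230.22	0	4	1	1.92	44.25
CHSGS128	Isodalbergin	268.26	1	4	2	3.76	35.45
CHSGS130	Khell	260.24	0	5	2	1.78	33.19
CHSGS134	Hyndarin	355.43	0	5	4	3.09	73.94
CHSGS141	Nonenoic acid	156.22	1	2	6	3.53	65.17
CHSGS143	3,5,6,7-tetramethoxy-2-(3,4,5-trimethoxyphenyl)chromone	432.42	0	9	8	2.59	31.97
CHSGS145	Ayapanin	176.17	0	3	1	2.06	41.55
CHSGS146	8-NONENOIC ACID	156.22	1	2	7	2.84	52.31
CHSGS149	Phenylacetic acid	136.15	1	2	2	1.72	72.35
CHSGS151	cis-2-Undecenal	168.28	0	1	8	4.93	47.07
CHSGS154	Ethyl protocatechuate	182.17	2	4	3	1.83	35.77
CHSGS160	(E)-non-2-en-4-one	140.22	0	1	5	2.98	37.78
CHSGS161	Cumic acid	164.2	1	2	2	2.86	45.78
CHSGS163	(2R)-2-amino-3-(1H-indol-3-yl)propionic acid	204.23	4	3	3	-1.1	75.63
CHSGS164	Veratryl alcohol	168.19	1	3	3	1.27	71.49
CHSGS171	(E)-1-(2,4-dihydroxyphenyl)-3-(2,2-dimethylchromen-6-yl)prop-2-en-1-one	322.35	2	4	3	4.46	39.62
CHSGS177	Karenzu DK2	224.25	0	2	4	3.14	62.26
CHSGS181	Gancaonin B	368.38	3	6	4	3.14	48.79
CHSGS184	2-(3,4-dihydroxyphenyl)-5,7-dihydroxy-6-(3-methylbut-2-enyl)chromone	354.35	4	6	3	2.99	44.15
CHSGS201	(-)-Medicocarpin	432.42	4	9	4	1.26	40.99
CHSGS206	3-(4-hydroxyphenyl)-7-methoxychromen-4-one	268.26	1	4	2	2.92	38.37
CHSGS207	1-Methoxyphaseollidin	354.4	2	5	3	3.66	69.98
CHSGS208	Quercetin der.	330.29	3	7	3	2.55	46.45
CHSGS209	(Z)-1-(2,4-dihydroxyphenyl)-3-phenylprop-2-en-1-one	240.25	2	3	3	3.3	73.18
CHSGS211	3′-Methoxyglabridin	354.4	2	5	2	3.76	46.16
CHSGS223	Glycyrrhiza flavonol A	370.35	4	7	1	2.18	41.28
CHSGS226	Phaseol	336.34	2	5	2	4.59	78.77
CHSGS227	Mipax	194.18	0	4	4	1.96	57.4
CHSGS228	5,7-dihydroxy-2-(3-hydroxy-4-methoxyphenyl)chroman-4-one	302.28	3	6	2	2.52	47.74
CHSGS234	Citromitin	404.41	0	8	7	2.61	86.9
CHSGS237	nobiletin	402.39	0	8	7	2.61	61.67
CHSGS238	7-Demethylsuberosin	230.26	1	3	2	3.41	41.19
CHSGS241	N-Methyltyramine	151.21	2	2	3	0.48	75.52
CHSGS245	Nerylacetone	194.31	0	1	6	4.59	45.53
CHSGS247	Cubebin	356.37	1	6	4	2.54	57.13
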