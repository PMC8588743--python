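species	listed_as	L	BD	EP	NR	NL	T	SL	GL	a	b	c	c_prime	SW_pct	GS_pct	D_pct	country	reference
H. amazonensis	H. amazonensis	692-826	36-43	96-116	71-88	97-114	29-41	35-45	19-23	18.7*	7.7**	27.5**	1.3**	120-187	44-56	95-109	Brazil	Andalo et al. 2006
H. atacamensis	H. atacamensis	842-1025	42-55	116-149	69-93	99-119	24-36	40-49	17-22	19.7*	9.6**	29.3**	1.5**	179-249	38-51	108-126	Chile	Edgington et al. 2011
H. bacteriophora	H. bacteriophora	780-960	38-46	114-130	65-81	99-105	22-36	36-44	18-25	20.8*	9.1*	34.3*	1.8*	174	50	117	Australia	Poinar 1976
H. bacteriophora	H. bacteriophora	700-940	37-50	113-140	70-85	95-110	20-27	39-47	18-24	NA	NA	NA	NA	NA	NA	NA	Argentina	Aguera de Doucet and Doucet 1986
H. bacteriophora	H. bacteriophora	689-880	38-46	78-123	55-90	92-124	21-32	34-48	17-26	NA	NA	NA	1.2*	147-256	41-49	68-106	Australia	Stock et al. 1996
H. bacteriophora	H. bacteriophora	782-927	92-120	103-139	58-76	84-105	28-37	51-53	17-26	6.6-8.5	8.5-10	23-32	1.4-2.2	194-282	37-57	108-157	India	Bhat et al. 2017
H. bacteriophora	H. bacteriophora	805-1075	42-57	84-111	84-75	80-119	24-39	39-51	17-27	16-22	7.1-12	22-41	1.0-1.7	170-225	40-62	77-136	India	Bhat et al. 2019
H. bacteriophora	H. argentinensis	1000-2000	42-70	145-170	64-82	103-120	28-49	42-49	20-26	16.7*	8.3*	14.3*	1.4*	198*	62*	92*	Argentina	Stock 1993
H. bacteriophora	H. heliothidis	1000-1200	32-60	125*	125*	113-131	29-36	42-52	22-27	19-35	8-11	28-38	1.3*	185*	51*	95*	USA	Khan et al. 1976
H. baujardi	H. baujardi	818-970	45-53	71-93	54-77	105-132	28-38	33-45	18-22	16-22	6.4-8.8	24-33	1.5**	138-208	44-61	79**	Vietnam	Phan et al. 2003
H. baujardi	H. baujardi	710-903	40-50	83-93	53-68	98-110	33-40	43-48	20-28	16-20	6.7-9.3	18-28	NA	154-200	47-61	80-90	India	Vanlalhlimpuia et al. 2018
H. baujardi	H. somsookae	737-870	37-44	68-93	72-83	90-120	20-30	32-45	17-23	20.7**	8.3**	32.3**	1.2**	133-198	42-59	74-99	Thailand	Maneesakorn et al. 2015
H. beicherriana	H. beicherriana	889-1192	51-73	130-157	81-108	116-143	32-45	40-49	22-27	15-23	7.2-10	22-34	1.3-2.3	153-208	48-59	102-120	China	Li et al. 2012
H. downesi	H. downesi	699-876	33-40	86-91	62-78	97-106	29-34	41-47	17-19	26.6*	8.8**	27.4**	1.4**	170-220	36-47	90	Ireland	Stock et al. 2002
H. egyptii	H. egyptii	594-848	31-56	80-97	56-84	96-109	23-34	25-50	16-22	17.1*	6.6**	19.5**	1.5*	120-220	40-65	84-91	Egypt	Abd-Elgawad and Ameen 2005
H. floridensis	H. floridensis	785-294	43-50	104-128	73-90	97-111	29-40	36-46	17-30	19.9*	7.9**	24.1**	1.4**	133-209	47-65	112	USA	Nguyen et al. 2006
H. georgiana	H. georgiana	721-913	43-55	101-145	72-93	100-122	29-41	41-49	20-28	16.5*	7.7**	26.1**	1.4**	150-200	51-64	100-122	USA	Nguyen et al. 2008
H. hambletoni	H. hambletoni	510-800	38-60	80-100	80-90	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	Brazil	Pereira 1937
H. hoptha	H. hoptha	554-837	NA	NA	NA	NA	30.9*	43-60	26-30	18-22	5.9-8.2	18-37	1.1*	167**	55**	NA	USA	Turco 1970
H. indica	H. indica	573-788	35-46	109-138	72-85	93-109	24-32	35-48	18-23	17.6*	6.7**	23.0**	1.1**	187	49	121	India	Poinar et al. 1992
H. indica	H. indica	724-864	41-48	96-113	63-80	89-109	29-36	30-40	21-31	17-20	7.6-8.6	22-27	1.4-1.8	155-210	49-68	101-111	India	Kumar et al. 2019
H. indica	H. indica	609-916	26-50	78-109	62-83	90-116	18-33	37-48	19-26	16-28	6.5-8.2	25-37	1.0-1.5	116-225	49-64	86-106	India	Bhat et al. 2021
H. indica	H. brevicaudis	840-950	40-48	92-100	80-88	104-112	28-36	44-48	20-24	NA	NA	NA	2.9*	170*	47*	84*	China	Liu 1994
H. indica	H. gerrardi	508-916	34-48	93-141	54-87	78-115	28-46	34-48	16-27	NA	NA	NA	NA	138-274	40-69	100-172	Australia	Plichta et al. 2009
H. indica	H. hawaiiensis	864-1130	49-84	71-146	67-112	100-149	26-40	40-51	18-26	NA	NA	NA	NA	NA	NA	NA	USA	Gardner et al. 1994
H. indica	H. pakistanense	720-1013	38-43	112-133	80-110	100-105	30-42	35-42	20-22	18-24	7.2-9.8	19-25	1.4**	144-191	48-65	110-126	Pakistan	Shahina et al. 2016
H. marelatus	H. marelatus	805-1046	48-56	110-168	61-95	99-123	24-38	41-49	18-22	15.5*	7.8**	30.0**	1.1**	196	36-50	113**	USA	Liu and Berry 1996
H. marelatus	H. marelatus	960-1010	48-80	107-116	89-95	115-130	37-47	48-52	21-24	NA	NA	NA	NA	NA	NA	NA	USA	Stock 1997
H. marelatus	H. hepialius	8000-1000	65-98	102-131	84-114	113-139	37-49	42-52	17-24	NA	NA	NA	NA	NA	NA	NA	USA	Stock et al. 1996b
H. megidis	H. megidis	800-1100	44-50	139-176	96-112	122-134	35-43	46-54	17-24	18-22	7-9	23-31	1.6*	188	43	122	USA	Poinar et al. 1987
H. mexicana	H. mexicana	614-801	38-47	108-145	61-83	89-108	21-36	30-47	18-32	21.7*	6.8**	27.6**	1.1**	130-196	43-70	114-149	Mexico	Nguyen et al. 2004
H. noenieputensis	H. noenieputensis	530-775	34-46	75-102	64-75	88-106	21-32	37-49	17-24	14-18	5.6-7.9	21-33	1.1-1.7	202-301	38-56	81-108	S. Africa	Malan et al. 2014
H. poinari	H. poinari	970-1100	43-70	NA	NA	150-150	36-65	43-55	24-32	95-100	51-95	11-97	NA	NA	NA	NA	USA	Kakuliya and Mikaia 1997
H. ruandica	H. ruandica	652-863	40-51	61-109	56-74	84-117	21-29	34-50	16-23	15-21	5.8-9.7	23-36	0.6-1.7	150-306	35-57	61-97	Rwanda	This study
H. safricana	H. safricana	777-1009	40-58	104-147	52-61	105-126	27-49	35-54	19-27	20.1*	7.9**	43.0**	1.5*	130-259	43-62	92-133	S. Africa	Malan et al. 2008
H. taysearae	H. taysearae	648-736	38-48	78-120	54-88	85-123	20-29	30-42	12-21	15.1*	6.5**	14.0**	1.3**	156	46	88	Egypt	Shamseldean et al. 1996
H. taysearae	H. sonorensis	500-750	32-42	60-84	60-80	80-100	25-45	31-45	20-31	NA	NA	NA	NA	110-180	40-75	72-91	Mexico	Stock et al. 2009
H. zealandica	H. zealandica	848-1044	36-45	130-150	NA	110-128	30-41	48-55	19-25	NA	NA	NA	1.7*	246	44	118	N. Zealand	Poinar 1990
H. zealandica	H. heliothidis	848-1044	36-45	130-150	NA	110-128	30-41	48-55	19-25	NA	NA	NA	1.7*	246	44	118	N. Zealand	Wouts 1979
H. zacatecana	H. zacatecana	811-914	41-56	77-109	60-78	71-108	21-33	38-55	15-25	15-25	7.6-12	26-43	1.2-2.5	170-320	40-60	78-134	Mexico	This study
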