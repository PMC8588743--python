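species	listed_as	L	BD	EP	NR	NL	T	a	b	c	c_prime	V	ABD	D_pct	country	reference
H. amazonensis	H. amazonensis	1279-2070	70-122	103-126	68-100	119-142	25-38	NA	NA	NA	2.4*	46-50	25-38	NA	Brazil	Andalo et al. 2006
H. atacamensis	H. atacamensis	1754-2628	86-129	154-182	79-119	129-167	80-108	NA	NA	NA	3.8*	43-49	24-33	100-113	Chile	Edgington et al. 2011
H. bacteriophora	H. bacteriophora	3180-3850	160-220	174-214	93-118	155-183	71-93	21.4*	18.8	41.5*	3.1*	42-53	22-31	114	Australia	Poinar 1976
H. bacteriophora	H. bacteriophora	1800-2400	100-162	122-162	83-102	108-145	40-65	NA	NA	NA	NA	41-50	23-40	NA	Argentina	Aguera de Doucet and Doucet 1986
H. bacteriophora	H. bacteriophora	1690-3214	100-224	101-212	67-103	120-163	54-101	NA	NA	NA	2.4*	44-50	21-24	72-137	Australia	Stock et al. 1996
H. bacteriophora	H. bacteriophora	1513-2290	84-150	128-181	71-99	113-135	41-79	11-22	11-19	26-42	1.6-2.5	38-51	24-39	108-150	India	Bhat et al. 2019a
H. bacteriophora	H. bacteriophora	1226-1819	58-115	108-157	68-91	101-127	29-94	16-25	7.8-16	16-48	1.0-3.4	44-58	24-31	83-116	India	Bhat et al. 2019
H. bacteriophora	H. argentinensis	2000-3500	90-180	105-240	88-140	162-200	75-108	12.5*	7.8*	31.2*	2.0*	42-48	33-35	100*	Argentina	Stock 1993
H. bacteriophora	H. heliothidis	2000-3300	184-240	146*	126*	148-177	71-93	11-15	14-21	26-46	2.8*	48-53	33*	95*	USA	Khan et al. 1976
H. baujardi	H. baujardi	1335-2130	90-150	104-149	75-122	131-185	68-89	12-16	10-12	19-32	NA	46-51	27-41	NA	Vietnam	Phan et al. 2003
H. baujardi	H. baujardi	2060-2290	120-150	98-115	80-95	123-148	78-108	15-17	16-18	20-27	NA	41-48	30-38	63-78	India	Vanlalhlimpuia et al. 2018
H. baujardi	H. somsookae	2159-2666	117-194	143-156	90-112	128-144	41-80	NA	NA	NA	2.9*	36-51	21-35	104-111	Thailand	Maneesakorn et al. 2015
H. beicherriana	H. beicherriana	1581-3026	125-218	95-165	59-138	105-186	68-105	10-18	10-23	19-34	1.6-2.4	41-49	35-81	88-98	China	Li et al. 2012
H. downesi	H. downesi	1231-2728	74-131	99-126	117-151	111-155	70-122	NA	NA	NA	2.5*	47-60	25-38	NA	Ireland	Stock et al. 2002
H. egyptii	H. egyptii	1050-1420	56-84	69-106	69-94	106-125	56-78	17.5**	14.4**	22.2**	3.1**	44-51	19-27	78**	Egypt	Abd-Elgawad and Ameen 2005
H. floridensis	H. floridensis	2054-2548	120-156	110-168	86-122	126-178	69-87	NA	NA	NA	NA	44-50	32-42	NA	USA	Nguyen et al. 2006
H. georgiana	H. georgiana	1640-2779	101-188	111-177	96-162	136-219	62-88	NA	NA	NA	1.5*	46-53	42*	NA	USA	Nguyen et al. 2008
H. hambletoni	H. hambletoni	600-1200	70-100	80-90	70-80	NA	NA	NA	NA	NA	NA	50-58**	NA	NA	Brazil	Pereira 1937
H. hoptha	H. hoptha	2826-3983	NA	148*	161*	219*	28*	13-19	12-21	47-67	0.8*	43-49	33*	92*	New Jersey	Turco 1970
H. indica	H. indica	1200-1800	76-113	118-138	88-96	120-139	66-88	NA	NA	NA	NA	40-53	22-32	NA	India	Poinar et al. 1992
H. indica	H. indica	1713-2242	110-156	135-172	77-92	120-138	61-83	13-17	11-18	22-36	1.9-2.9	44-50	27-33	102-128	India	Kumar et al. 2019
H. indica	H. indica	1274-1993	70-135	105-129	84-111	124-155	64-83	12-18	10-13	16-31	2.6-4.9	45-52	22-30	77-99	India	Bhat et al. 2021b
H. indica	H. brevicaudis	2100-2500	128-168	124-160	100-108	144-160	76-92	NA	NA	NA	NA	45-53	36-48	NA	China	Liu 1994
H. indica	H. gerrardi	1428-2533	71-161	108-157	73-141	120-182	66-95	NA	NA	NA	3.3*	43-55	22-38	74-112	Australia	Plichta et al. 2009
H. indica	H. hawaiiensis	1300-2300	104-171	116-175	78-116	110-153	49-87	NA	NA	NA	NA	49-56	20-35	NA	USA	Gardner et al. 1994
H. indica	H. pakistanense	1413-1785	71-86	130-150	80-100	130-145	65-95	19-21	11-12	16-22	3.1*	44-53	24-27	95*	Pakistan	Shahina et al. 2016
H. marelatus	H. marelatus	1600-2600	113-177	139-178	79-119	129-164	55-81	NA	NA	NA	1.3*	45-50	29-48	110*	USA	Liu and Berry 1996
H. marelatus	H. marelatus	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	USA	Stock 1997
H. marelatus	H. hepialius	3500-4500	99-161	133-177	99-135	150-183	76-113	18*	13*	27*	1.3*	49-51	24-60	88*	USA	Stock et al. 1996b
H. megidis	H. megidis	1500-2500	95-140	158-206	105-120	155-168	70-101	15-19	10-16	18-32	2.6*	47-51	25-38	119*	USA	Poinar et al. 1987
H. mexicana	H. mexicana	1144-2108	65-123	114-148	76-103	121-150	76-106	NA	NA	NA	NA	44-51	21-36	NA	Mexico	Nguyen et al. 2004
H. noenieputensis	H. noenieputensis	1075-1697	76-129	102-125	73-90	115-132	63-75	13-17	9-14	17-24	2.3-3.1	40-53	22-32	83-104	S. Africa	Malan et al. 2014
H. poinari	H. poinari	910-1520	62-80	NA	NA	152-172	86-105	11-14	50-51	10-11	NA	38-50	NA	NA	USA	Kakuliya and Mikaia 1997
H. ruandica	H. ruandica	1131-1608	68-83	92-129	69-97	107-132	62-88	15-20	9.0-14	16-24	1.9-3.6	41-51	18-34	74-104	Rwanda	This study
H. safricana	H. safricana	1679-2937	102-229	151-196	87-139	148-180	55-111	NA	NA	NA	1.3*	45-50	25-72	97-120	S. Africa	Malan et al. 2008
H. taysearae	H. taysearae	830-1400	42-96	120-166	76-109	129-179	62-80	NA	NA	NA	4.0*	44-73	19-28	82*	Egypt	Shamseldean et al. 1996
H. taysearae	H. sonorensis	1500-2500	85-210	95-140	85-105	129-215	75-99	NA	NA	NA	3.5*	49-53	36-46	93*	Mexico	Stock et al. 2009
H. zealandica	H. zealandica	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	N. Zealand	Poinar 1990
H. zealandica	H. heliothidis	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	N. Zealand	Wouts 1979
H. zacatecana	H. zacatecana	1954-2798	160-228	100-133	71-96	112-148	45-75	11-15	16-21	31-63	1.3-2.0	43-61	31-41	80-111	Mexico	This study
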