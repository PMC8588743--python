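species	listed_as	L	BD	EP	NR	NL	T	a	b	c	c_prime	D_pct	E_pct	country	reference
H. amazonensis	H. amazonensis	567-612	20-24	89-115	76-93	107-132	98-115	24-29	4.4-5.5	5.1-6.1	7.3*	83-92	89-109	Brazil	Andalo et al. 2006
H. atacamensis	H. atacamensis	578-666	19-26	101-126	79-101	124-144	94-107	25-31	4.8-5.7	5.7-7.1	5.7*	79-94	149-182	Chile	Edgington et al. 2011
H. bacteriophora	H. bacteriophora	512-671	18-31	87-110	72-93	100-139	83-112	17-30	4.0-5.1	5.7-7.0	6.0*	76-92	103-130	Australia	Poinar 1976
H. bacteriophora	H. bacteriophora	530-660	22-30	93-108	80-90	110-130	84-105	23*	4.4*	5.7*	4.8*	81*	106*	Argentina	Aguera de Doucet and Doucet 1986
H. bacteriophora	H. bacteriophora	537-587	19-22	87-104	67-83	112-121	94-111	25-31	3.3-3.6	3.6-4.6	7.0*	73-88	87-105	Australia	Stock et al. 1996
H. bacteriophora	H. bacteriophora	474-568	22-28	110-127	61-90	90-115	57-90	19-25	4.7-6.1	5.5-9.3	3.4-7.5	105-139	131-211	India	Bhat et al. 2019a
H. bacteriophora	H. bacteriophora	453-167	19-27	72-102	50-74	83-106	47-89	19-29	4.9-7.4	6.0-12	3.7-6.5	78-107	105-189	India	Bhat et al. 2019
H. bacteriophora	H. argentinensis	610-710	24-38	68-112	82-116	101-150	70-105	18.3*	3.7*	6.5*	4.3*	80*	141*	Argentina	Stock 1993
H. bacteriophora	H. heliothidis	619-671	23-29	112*	108*	130-139	104-112	22-28	4.6-5.4	5.8-6.3	6.0*	83*	97*	USA	Khan et al. 1976
H. baujardi	H. baujardi	497-595	18-22	91-103	75-86	107-120	83-97	26-30	4.5-5.1	6-6.7	7.2*	78-88	98-114	Vietnam	Phan et al. 2003
H. baujardi	H. baujardi	525-615	18-25	88-96	68-85	98-120	95-108	24-32	4.6-5.9	5.2-6.1	NA	74-86	89-92	India	Vanlalhlimpuia et al. 2018
H. baujardi	H. somsookae	502-565	19-23	81-95	78-94	106-117	91-131	23-27	5-5	4-6	8.0*	76-87	64-95	Thailand	Maneesakorn et al. 2015
H. beicherriana	H. beicherriana	566-687	21-25	100-122	85-106	118-146	86-111	24-29	4.2-4.9	5.9-6.8	6.0-7.4	80-93	103-121	China	Li et al. 2012
H. downesi	H. downesi	588-692	15-22	96-128	96-105	126-141	62-74	29-42	4.4-5.3	8.5-10.5	4.4*	76-96	160-180	Ireland	Stock et al. 2002
H. egyptii	H. egyptii	484-515	18-23	81-94	78-100	100-119	53-75	20-27	4.2-5.2	6.8-9.1	6.9*	74-82	100-170	Egypt	Abd-Elgawad and Ameen 2005
H. floridensis	H. floridensis	554-609	19-23	101-122	68-107	123-142	91-113	25-32	3.9-4.9	5.3-6.6	7.2*	71-90	95-134	USA	Nguyen et al. 2006
H. georgiana	H. georgiana	547-651	17-26	97-113	74-94	110-139	86-108	23-34	4.1-5.3	5.5-6.9	6.8*	70-93	106	USA	Nguyen et al. 2008
H. hambletoni	H. hambletoni	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	Brazil	Pereira 1937
H. hoptha	H. hoptha	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	USA	Turco 1970
H. indica	H. indica	479-573	19-22	88-107	72-85	109-123	93-109	25-27	4.3-4.8	4.5-5.6	NA	79-90	83-103	India	Poinar et al. 1992
H. indica	H. indica	511-546	21-24	92-108	63-73	86-103	24-34	22-25	5-6	4.6-5.4	2.8-5.2	77-96	100-118	India	Kumar et al. 2019
H. indica	H. indica	516-598	21-25	98-123	82-101	102-129	80-112	24-27	4.5-5.4	4.9-5.7	5.6-8.1	83-97	93-136	India	Bhat et al. 2021b
H. indica	H. brevicaudis	528-632	20-24	104-116	96-104	120-136	68-80	NA	NA	6.6-8.6	6.3*	81*	150-180	China	Liu 1994
H. indica	H. gerrardi	551-682	18-29	92-111	81-105	110-130	76-141	23-32	16-23	11-21	6.8*	73-92	73-138	Australia	Plichta et al. 2009
H. indica	H. hawaiiensis	506-631	21-28	116-175	79-103	115-181	82-108	NA	NA	NA	6.0*	77*	88*	USA	Gardner et al. 1994
H. indica	H. pakistanense	558-624	19-23	95-106	73-90	113-125	95-110	25-29	4.7-5.3	5.4-6.2	5.4*	78-97	95-107	Pakistan	Shahina et al. 2016
H. marelatus	H. marelatus	588-700	24-32	81-113	83-113	121-139	99-117	21-29	4.7-5.4	5.5-6.6	3.0*	60-86	89-110	USA	Liu and Berry 1996
H. marelatus	H. marelatus	567-780	16-24	88-94	71-88	110-119	50-71	31-35	5.1-6.5	10.8-11.5	NA	73-88	130-142	USA	Stock 1997
H. marelatus	H. hepialius	540-600	34-39	84-112	80-101	106-130	49-60	5-7	4-5	9-12	NA	79-98	100-200	USA	Stock et al. 1996b
H. megidis	H. megidis	736-800	27-32	123-142	104-115	147-160	112-128	23-38	4.6-5.9	6.1-6.9	6.3*	81-91	103-120	USA	Poinar et al. 1987
H. mexicana	H. mexicana	530-620	20-24	83-109	74-88	104-142	91-106	24-28	4.2-5.1	5.5-6.3	8.3*	72-86	87-111	Mexico	Nguyen et al. 2004
H. noenieputensis	H. noenieputensis	484-578	21-25	88-105	69-96	79-115	78-95	21-27	4.3-5.2	5.5-6.8	3.4-4.3	81-95	99-125	S. Africa	Malan et al. 2014
H. poinari	H. poinari	350-410	18-22	NA	NA	NA	15-22	NA	NA	NA	NA	NA	NA	USA	Kakuliya and Mikaia 1997
H. ruandica	H. ruandica	496-591	18-27	70-89	52-64	103-131	49-64	20-29	4.1-5.4	7.6-8.6	3.4-5.8	66-98	112-168	Rwanda	This study
H. safricana	H. safricana	550-676	19-23	103-122	86-101	125-141	86-108	25-32	3.9-4.9	5.4-7.5	8.7*	80-90	99-133	S. Africa	Malan et al. 2008
H. taysearae	H. taysearae	332-499	17-23	74-113	58-87	96-130	44-70	18-27	3.4-4.2	6.5-8.7	3.7*	71-96	110-230	Egypt	Shamseldean et al. 1996
H. taysearae	H. sonorensis	495-570	19-32	97-116	87-98	110-131	91-125	19-26	4.4-5.4	4.0-6.5	6.7*	78-110	81-111	Mexico	Stock et al. 2009
H. zealandica	H. zealandica	570-740	22-30	94-123	90-107	135-147	87-119	25	4.9	6.7	NA	73-92	103-109	N. Zealand	Poinar 1990
H. zealandica	H. heliothidis	570-740	22-30	94-123	90-107	135-147	87-119	25	4.9	6.7	NA	73-92	103-109	N. Zealand	Wouts 1979
H. zacatecana	H. zacatecana	493-578	23-27	72-99	69-72	96-124	52-63	19-24	4.4-5.9	8.2-10.5	4.3-6.7	68-120	128-184	Mexico	This study
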