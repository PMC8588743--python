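species	listed_as	L	BD	EP	NR	NL	T	a	b	c	c_prime	V	ABD	D_pct	country	reference
H. amazonensis	H. amazonensis	3517-5587	220-316	184-238	128-171	180-225	104-154	NA	NA	NA	2.3*	42-47	59-83	103*	Brazil	Andalo et al. 2006
H. atacamensis	H. atacamensis	1791-2904	88-122	165-206	101-132	174-200	72-112	NA	NA	NA	2.7*	39-48	30-46	90-114	Chile	Edgington et al. 2011
H. bacteriophora	H. bacteriophora	3630-4390	160-180	189-217	121-130	189-205	81-93	NA	NA	NA	NA	41-47	40-53	106	Australia	Poinar 1976
H. bacteriophora	H. bacteriophora	4200-5600	175-242	163-225	125-152	180-220	50-87	NA	NA	NA	NA	35-45	45-62	NA	Argentina	Aguera de Doucet and Doucet 1986
H. bacteriophora	H. bacteriophora	2686-4893	131-241	150-379	80-196	162-302	70-120	NA	NA	NA	1.8*	36-52	43-76	76-126	Australia	Stock et al. 1996
H. bacteriophora	H. bacteriophora	3086-5492	221-352	127-260	79-162	101-200	71-123	9.2-28	23-37	25-75	1.2-3.7	37-52	34-75	112-155	India	Bhat et al. 2019a
H. bacteriophora	H. bacteriophora	3916-5155	205-206	153-198	94-127	158-207	70-98	17-21	21-28	46-69	1.7-2.2	37-46	39-51	75-103	India	Bhat et al. 2019
H. bacteriophora	H. argentinensis	5000-7500	250-575	250-340	132-196	235-300	100-140	NA	NA	NA	1.8*	40-50	70-120	102*	Argentina	Stock 1993
H. bacteriophora	H. heliothidis	3000-5100	200-344	250*	250*	163-286	76-100	11-18	11-25	30-63	2.2*	45-52	62.5*	80*	USA	Khan et al. 1976
H. baujardi	H. baujardi	3135-4170	180-240	156-192	119-147	186-206	66-114	15-19	16-21	36-50	2.0*	43-48	47-63	88*	Vietnam	Phan et al. 2003
H. baujardi	H. baujardi	3250-3970	190-250	98-115	120-135	180-205	80-105	13-19	16-20	31-45	NA	41-49	50-65	73-92	India	Vanlalhlimpuia et al. 2018
H. baujardi	H. somsookae	2275-3952	108-183	156-214	118-144	158-193	56-87	NA	NA	NA	2.3*	41-56	30-53	86-113	Thailand	Maneesakorn et al. 2015
H. beicherriana	H. beicherriana	3671-5543	198-374	165-297	135-243	192-343	68-130	13-20	13-25	34-62	1.0-2.3	41-49	51-92	76-94	China	Li et al. 2012
H. downesi	H. downesi	3030-5051	183-291	200-254	175-230	230-244	60-70	NA	NA	NA	1.1*	50-55	57-65	117*	Ireland	Stock et al. 2002
H. egyptii	H. egyptii	2100-3100	107-164	154-205	101-147	144-192	83-115	NA	NA	NA	2.7*	46-59	33-51	104*	Egypt	Abd-Elgawad and Ameen 2005
H. floridensis	H. floridensis	3731-5865	217-331	211-301	169-271	271-391	84-126	NA	NA	NA	2.5*	44-49	42-78	104*	USA	Nguyen et al. 2006
H. georgiana	H. georgiana	3232-4928	157-267	200-277	143-217	132-271	65-96	NA	NA	NA	1.2*	44-55	42.6*	NA	USA	Nguyen et al. 2008
H. hambletoni	H. hambletoni	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	Brazil	Pereira 1937
H. hoptha	H. hoptha	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	USA	Turco 1970
H. indica	H. indica	2300-3100	107-145	163-187	104-123	163-179	72-110	NA	NA	NA	NA	45-50	38-51	NA	India	Poinar et al. 1992
H. indica	H. indica	2751-4481	168-273	184-238	115-157	167-204	67-108	16-18	15-25	35-55	1.4-2.5	37-48	30-71	103-132	India	Kumar et al. 2019
H. indica	H. indica	2861-4227	152-208	140-179	119-146	165-186	79-114	16-23	17-24	30-47	1.5-2.4	39-55	37-56	81-100	India	Bhat et al. 2021b
H. indica	H. brevicaudis	3550-5040	200-312	160-200	144-176	192-240	72-128	NA	NA	NA	NA	37-50	56-88	91*	China	Liu 1994
H. indica	H. gerrardi	2049-4288	93-209	103-288	82-210	146-317	90-196	NA	NA	NA	2.4*	40-48	40-80	90-147	Australia	Plichta et al. 2009
H. indica	H. hawaiiensis	4000-7000	270-376	219-318	102-212	187-283	67-98	NA	NA	NA	NA	NA	38-79	NA	USA	Gardner et al. 1994
H. indica	H. pakistanense	1939-4625	102-240	145-186	130-180	155-220	64-95	16-23	11-24	23-58	1.7*	41-49	37-55	68-106	Pakistan	Shahina et al. 2016
H. marelatus	H. marelatus	3000-4500	161-233	212-287	133-182	190-244	75-101	NA	NA	NA	1.3*	45-50	20-28	109*	USA	Liu and Berry 1996
H. marelatus	H. marelatus	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	USA	Stock 1997
H. marelatus	H. hepialius	4000-5200	205-335	175-258	117-161	190-223	60-126	NA	NA	NA	1.9*	45-50	34-60	NA	USA	Stock et al. 1996b
H. megidis	H. megidis	2400-4900	120-133	193-270	139-178	106-269	95-124	14-24	12-21	23-49	NA	45-50	36-86	NA	USA	Poinar et al. 1987
H. mexicana	H. mexicana	2440-4606	135-267	103-201	114-171	168-221	94-170	NA	NA	NA	2.6*	30-58	40-46	90*	Mexico	Nguyen et al. 2004
H. noenieputensis	H. noenieputensis	2987-5498	168-289	152-209	112-152	166-220	79-120	14-23	18-28	37-58	1.7-3.4	39-47	26-56	77-112	S. Africa	Malan et al. 2014
H. poinari	H. poinari	1350-2800	54-105	NA	NA	NA	108-112	NA	NA	NA	NA	NA	NA	NA	USA	Kakuliya and Mikaia 1997
H. ruandica	H. ruandica	2907-4123	209-274	106-153	78-108	134-159	63-98	12-16	21-27	34-51	1.7-2.6	45-55	29-51	67-103	Rwanda	This study
H. safricana	H. safricana	3373-4073	127-188	210-267	121-163	199-236	64-91	NA	NA	NA	NA	43-46	40-54	98-119	S. Africa	Malan et al. 2008
H. taysearae	H. taysearae	2200-2800	116-170	137-182	83-120	161-200	72-100	NA	NA	NA	NA	40-64	41-67	NA	Egypt	Shamseldean et al. 1996
H. taysearae	H. sonorensis	2856-5799	150-200	115-203	105-180	133-215	122-178	NA	NA	NA	3.0*	50-58	40-75	NA	Mexico	Stock et al. 2009
H. zealandica	H. zealandica	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	N. Zealand	Poinar 1990
H. zealandica	H. heliothidis	4000*	247*	NA	181*	236	90*	16*	17*	44*	1.7*	46*	53*	NA	N. Zealand	Wouts 1979
H. zacatecana	H. zacatecana	4408-6179	235-385	108-190	96-169	174-231	63-87	13-20	20-34	52-90	1.2-2.4	36-57	34-58	55-95	Mexico	This study
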