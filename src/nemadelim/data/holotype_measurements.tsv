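specimen_id	species	stage	L	BD	lip	stoma	BL	PL	NR	EP	NL	ABD	T	SL	GL
Rw14_N-C4a_holotype	H. ruandica	male	760	37.5	6.5	9.5	18.5	95.2	68	84.3	98	26.1	29	49	20.2
MEX-39_holotype	H. zacatecana	male	808.1	42.5	6.2	10	20.2	95.2	65.4	96.2	99.3	19.6	28	54.1	18.7
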