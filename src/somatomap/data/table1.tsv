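Participants	Age	Gender	Handedness (prior to amputation for amputees)	Affected limb	Level of limb deficiency	Years since amputation	PLS intensity	PLS frequency	Chronic PLS	PLP intensity	PLP frequency	Chronic PLP	Cause of amputation
AA01	60	M	R	R	2	43	100	5	100	60	5	60	Trauma
AA02	34	M	R	R	1	3	50	2.5	14.6	70*	2	17.5*	Trauma
AA03	58	M	R	R	1	33	90	5	90	100	1	20	Trauma
AA04	59	M	R	L	2	16	40	1	8	0	1	0	Trauma
AA05	54	M	A	L	1	36	100	5	100	80	4	40	Trauma
AA06	47	F	R	L	2	18	80	4	40	0	0	0	Electrocution
AA08	40	F	R	R	1	10	40	3	13.3	0	0	0	Trauma
AA09	47	M	R	R	2	5	70	4	35	10	4	5	Trauma
AA10	53	M	R	L	2	34	20	0	0	0	0	0	Trauma
AA11	56	F	L	L	1	12	90	5	90	80	5	80	Tumour
AA12	66	M	R	R	1	38	60	5	60	0	0	0	Trauma
AA13	65	F	L	L	1	10	90	5	90	80	4	40	Trauma
AA14	66	M	R	L	1	35	80	2	20	100	2	25	Trauma
AA16	64	M	R	R	1	18	75	5	75	65	5	65	Trauma
AA17	65	M	R	R	1	8	70	5	70	0	0	0	Trauma
AA18	48	M	R	R	1	23	85	5	85	65	5	65	Trauma
AA19	31	M	R	L	2	14	30	5	30	25	1	5	Trauma
CA01	32	F	R	L	2
CA02	32	F	R	L	2
CA03	35	M	R	L	2
CA04	48	M	R	L	2
CA05	22	F	L	R	2
CA06	54	F	R	L	2
CA07	56	F	L	R	2
CA08	53	M	R	L	1
CA09	54	F	R	L	2
CA10	58	M	L	R	2
CA11	22	M	R	L	2
CA12	30	F	R	L	2
CA13	24	M	L	R	2
CA14	33	F	L	R	2
CA15	39	F	L	R	2
CA16	55	F	R	L	2
CA17	67	F	L	R	2
CA18	30	F	L	R	2
CA19	43	M	R	L	2
CA20	63	M	R	L	2
CA21	46	F	R	L	2
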