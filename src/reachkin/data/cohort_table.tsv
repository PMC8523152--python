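Participant	Age	Y since amp	Gender	Amp side	Amp level	Amp cause	Artificial arm type	Artificial arm wear time	PAL	Usage score	Age at first artificial arm use	Years of limbless experience	Residual limb length
ALD01	58	14	M	L	TR	Trauma	Myo	119	0.5	1.87		0.5	15
ALD02	46	16	F	L	TR	Trauma	Myo	56	0.59	0.49		0.5	14
ALD03*	50	3	F	L	TR	Trauma	Mech	77	0.44	0.44			18
ALD04*	53	34	M	L	TH	Trauma	Mech	48	0.2	-1.4		0.33
ALD05	21	1	M	R	TR	Trauma	None	0	0.04	-3.44		0.083	34
ALD06*	42	18	M	R	TR	Trauma	Cos	35	0.07	-2.33			16
ALD07	61	21	M	L	TR	Trauma	Cos	105	0.67	2.21		0.125	29.5
ALD08	60	42	M	R	TR	Trauma	Mech	87.5	0.28	0.05		3.5	9
ALD09*	65	37	M	R	TH	Trauma	Mech	98	0.46	1.11		0.25
ALD10*	47	21	M	R	TH	Trauma	Cos	84	0.3	0.03		1
ALD11	68	12	M	L	TR	Trauma	Mech	35	0.54	-0.31		0.33	21.5
ALD12	49	5	M	R	TR	Vascular disease	Cos	42	0.59	0.1		0.5	20
ALD13	57	29	M	L	TR	Trauma	Mech	65	0.11	-1.31		1	18
ALD14	53	33	M	L	TR	Trauma	Myo	98	0.43	0.98		0.67	12
ALD15*	28	10	F	R	TR	Trauma	Mech	2	0	-3.55		5	7.5
ALD16	29	11	M	L	TR	Trauma	None	0	0	-3.61		2	28.5
ALD17	43	20	M	R	TR	Trauma	Myo	98	0.61	1.75		0.083	8
ALD18	55	12	M	L	TR	Trauma	Myo	98	0.65	1.92		0.5	33
ALD19	61	17	M	L	TR	Trauma	Mech	91	0.74	2.11		1	18
ALD21	30	3	M	L	TR	Trauma	Myo	49	0.59	0.29		0.54	20.5
CLD01	51		F	L	TR	Congenital	Cos	7	0.26	-2.3	0.5		10
CLD02	47		M	L	TR	Congenital	Mech	84	0.7	1.75	1		13
CLD03	45		F	L	TR	Congenital	Myo	63	0.46	0.13	4.5		8
CLD04*	26		M	L	TR	Congenital	Mech	6	0.13	-2.88	0.25		15
CLD05*	55		F	L	TR	Congenital	Cos	112	0.3	0.82	0.25		6
CLD06	63		M	L	TR	Congenital	Cos	87.5	0.35	0.35	2		10
CLD07	35		M	L	TR	Congenital	Cos	56	0.28	-0.84	3		11
CLD09	49		M	L	TR	Congenital	Myo	91	0.57	1.39	2		21
CLD10	42		M	L	TR	Congenital	Cos	56	0.54	0.28	2		10.5
CLD11	66		F	R	TR	Congenital	Cos	42	0.35	-0.93	5		9
CLD12	56		F	R	TR	Congenital	Cos	98	0.43	0.98	3		11.5
CLD13*	53		M	L	TH	Congenital	Mech	63	0.33	-0.43	2
CLD14	42		M	L	TR	Congenital	Mech	2	0.09	-3.17	4		12
CLD15	55		F	L	TR	Congenital	Myo	105	0.65	2.12	3		11.5
CLD17	29		M	L	TR	Congenital	Myo	70	0.46	0.33	1		12
CLD18	53		F	L	TR	Congenital	Cos	48	0.65	0.52	1.5		7
CLD20	52		F	R	TR	Congenital	Myo	32.5	0.26	-1.58	0.3		11.5
CLD21	32		F	R	TR	Congenital	Myo	40	0.41	-0.73	0.5		9
CLD22	57		M	R	TR	Congenital	Mech	126	0.69	2.88	2		15.5
CLD23	47		F	L	TR	Congenital	Myo	84	0.89	2.56	11		8.5
CLD25	41		M	L	TR	Congenital	Myo	112	0.85	3.17	0.25		8
CO01	28		F	L
CO03	40		F	L
CO04	59		M	L
CO05	27		F	R
CO06	61		F	L
CO07	35		M	L
CO08	34		F	L
CO09	24		M	L
CO10*	70		M	L
CO11	24		M	L
CO12	18		F	L
CO13	67		M	L
CO14	50		M	R
CO15	51		F	L
CO16	36		F	L
CO17	41		M	R
CO18	33		M	R
CO19	45		M	R
CO20	54		M	R
CO21	53		M	L
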