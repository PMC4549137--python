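id	group	age	gender	years_of_symptoms	cag_expansion	sara
P01	patient	40	F	21	50	27
P02	patient	44	F	6	44	9
P03	patient	68	F	1	50	6
P04	patient	43	F	21	47	15
P05	patient	42	F	17	47	29.5
P06	patient	18	M	15	50	19.5
P07	patient	39	F	23	50	27
P08	patient	18	F	4	53	7
P09	patient	19	M	7	71	29.5
P10	patient	34	M	10	55	17
P11	patient	35	M	14	52	16
P12	patient	64	M	10	43	14.5
P13	patient	47	M	6	50	13
P14	patient	23	M	3	61	12.5
P15	patient	52	M	7	46	12
P16	patient	44	M	4	48	11
P17	patient	40	F	13	55	23
P18	patient	60	M	6	45	16
P19	patient	54	M	6	43	24
P20	patient	45	F	7	44	12
P21	patient	35	F	1	42	8.5
P22	patient	21	F	1	46	4
P23	patient	20	M	1	48	4
P24	patient	30	M	6	48	12
P25	patient	61	M	7	41	10.5
P26	patient	29	M	7	48	26
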