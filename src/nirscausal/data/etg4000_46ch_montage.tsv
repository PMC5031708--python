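id	x	y	z	ba	aal
1	-54	36	3	45	L IFGtriang
2	-40	59	6	10	L MFG
3	-60	16	14	44	L IFGoperc
4	-48	45	16	45	L MFG
5	-29	63	18	10	L SFGdor
6	-54	27	26	45	L IFGtriang
7	-37	50	27	46	L MFG
8	-59	5	35	6	L PreCG
9	-45	33	37	45	L MFG
10	-24	52	38	9	L SFGdor
11	-49	14	48	9	L MFG
12	-32	36	47	9	L MFG
13	42	59	8	46	R MFG
14	57	35	5	45	R IFGtriang
15	31	63	20	10	R SFGdor
16	50	45	18	45	R MFG
17	64	14	16	6	R IFGoperc
18	39	51	29	46	R MFG
19	56	27	28	45	R IFGtriang
20	25	52	39	9	R SFGdor
21	45	34	40	9	R MFG
22	61	5	38	6	R PreCG
23	31	37	49	9	R MFG
24	49	14	50	9	R MFG
25	-42	-69	51	39	L ANG
26	-18	-80	55	7	L SPG
27	16	-80	54	7	R SPG
28	41	-71	51	7	R ANG
29	-53	-69	38	39	L ANG
30	-31	-86	40	19	L MOG
31	-3	-89	38	19	L CUN
32	27	-88	38	19	R SOG
33	52	-71	36	39	R ANG
34	-42	-87	26	19	L MOG
35	-17	-98	26	18	L SOG
36	14	-98	25	18	R SOG
37	38	-89	24	19	R MOG
38	-51	-81	11	19	L MOG
39	-28	-99	12	17	L MOG
40	-4	-104	13	17	L SOG
41	25	-101	11	17	R SOG
42	48	-84	8	19	R MOG
43	-38	-94	-2	18	L MOG
44	-16	-106	0	17	L MOG
45	15	-105	0	17	R CAL
46	35	-96	-4	18	R IOG
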