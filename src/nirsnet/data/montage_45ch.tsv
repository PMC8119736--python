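channel	source	detector	length_mm	x	y	z	roi	label
1	TP7	T7	20	-45	-25	-2	LTL	Middle temporal gyrus left
2	TP7	P7	25	-41	-42	-1	LTL	Middle temporal gyrus left
3	FT7	T7	20	-45	-8	-2	LTL	Temporal pole (superior) left
4	FT7	F7	20	-41	10	-3	LTL	Superior temporal gyrus left
5	FC5	T7	25	-46	-7	8	LTL	Heschl gyrus left
6	FC5	F7	25	-42	11	7	LTL	Inferior frontal gyrus (opercular) left
7	FC5	C3	30	-44	-6	31	LPL	Postcentral gyrus left
8	FC5	F3	25	-41	14	26	LPL	Middle frontal gyrus left
9	CP5	P7	25	-43	-44	10	LTL	Middle temporal gyrus left
10	CP5	C3	30	-47	-27	32	LPL	Inferior parietal lobule left
11	CP5	P3	25	-42	-48	30	LPL	Angular gyrus left
12	AF7	F7	20	-37	26	-2	LPFC	Inferior frontal gyrus (triangular) left
13	AF7	Fp1	25	-26	39	-2	LPFC	Middle frontal gyrus left
14	AF3	F3	25	-29	34	25	LPFC	Middle frontal gyrus left
15	AF3	Fp1	25	-17	44	10	LPFC	Superior frontal gyrus (dorsal) left
16	CP1	C3	30	-35	-27	55	LPL	Postcentral gyrus left
17	CP1	P3	30	-31	-50	47	LPL	Superior parietal gyrus left
18	FC1	C3	30	-33	-5	50	LPL	Precentral gyrus left
19	FC1	F3	30	-30	17	42	LPL	Middle frontal gyrus left
20	FC1	Fz	30	-14	17	53	LPL	Superior frontal gyrus (dorsal) left
21	FC1	Cz	30	-15	-4	61	LPL	Supplementary motor area left
22	AFz	Fp1	30	-10	45	13	LPFC	Superior frontal gyrus (medial) left
23	AFz	Fz	25	-2	36	37	MIDLINE	Superior frontal gyrus (medial)
24	AFz	Fp2	30	7	45	14	RPFC	Superior frontal gyrus (medial) right
25	AF4	Fp2	25	14	43	11	RPFC	Superior frontal gyrus (dorsal) right
26	AF4	F4	25	25	32	28	RPFC	Middle frontal gyrus right
27	FC2	Fz	30	6	18	53	RPL	Superior frontal gyrus (dorsal) right
28	FC2	Cz	30	7	-3	61	RPL	Supplementary motor area right
29	FC2	F4	30	24	16	45	RPL	Middle frontal gyrus right
30	FC2	C4	30	27	-4	52	RPL	Middle frontal gyrus right
31	AF8	Fp2	25	23	38	0	RPFC	Middle frontal gyrus right
32	AF8	F8	20	32	25	0	RPFC	Inferior frontal gyrus (triangular) right
33	CP2	C4	30	28	-26	56	RPL	Postcentral gyrus right
34	CP2	P4	30	26	-50	50	RPL	Superior parietal gyrus right
35	FC6	F4	25	35	13	30	RPL	Middle frontal gyrus right
36	FC6	F8	25	37	10	11	RTL	Inferior frontal gyrus (opercular) right
37	FC6	C4	30	39	-5	34	RPL	Postcentral gyrus right
38	FC6	T8	25	41	-6	11	RTL	Heschl gyrus right
39	FT8	F8	20	36	8	0	RTL	Superior temporal gyrus right
40	FT8	T8	20	40	-7	0	RTL	Temporal pole (superior) right
41	CP6	C4	30	41	-26	37	RPL	Inferior parietal lobule right
42	CP6	P4	25	37	-46	34	RPL	Angular gyrus right
43	CP6	P8	25	40	-43	14	RTL	Middle temporal gyrus right
44	TP8	T8	20	41	-24	1	RTL	Middle temporal gyrus right
45	TP8	P8	25	38	-41	2	RTL	Middle temporal gyrus right
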