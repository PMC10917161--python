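scale1_id	scale1_name	scale2_id	scale2_name	scale3_id	scale3_name	scale4_id	scale4_name	scale5_id	scale5_name
1	SFG_L	1	SFG_L	1	Frontal_L	1	CerebralCortex_L	1	Telencephalon_L
2	SFG_R	2	SFG_R	2	Frontal_R	2	CerebralCortex_R	2	Telencephalon_R
3	SFG_PFC_L	1	SFG_L	1	Frontal_L	1	CerebralCortex_L	1	Telencephalon_L
4	SFG_PFC_R	2	SFG_R	2	Frontal_R	2	CerebralCortex_R	2	Telencephalon_R
5	SFG_pole_L	1	SFG_L	1	Frontal_L	1	CerebralCortex_L	1	Telencephalon_L
6	SFG_pole_R	2	SFG_R	2	Frontal_R	2	CerebralCortex_R	2	Telencephalon_R
7	MFG_L	3	MFG_L	1	Frontal_L	1	CerebralCortex_L	1	Telencephalon_L
8	MFG_R	4	MFG_R	2	Frontal_R	2	CerebralCortex_R	2	Telencephalon_R
9	MFG_DPFC_L	3	MFG_L	1	Frontal_L	1	CerebralCortex_L	1	Telencephalon_L
10	MFG_DPFC_R	4	MFG_R	2	Frontal_R	2	CerebralCortex_R	2	Telencephalon_R
11	IFG_opercularis_L	5	IFG_L	1	Frontal_L	1	CerebralCortex_L	1	Telencephalon_L
12	IFG_opercularis_R	6	IFG_R	2	Frontal_R	2	CerebralCortex_R	2	Telencephalon_R
13	IFG_orbitalis_L	5	IFG_L	1	Frontal_L	1	CerebralCortex_L	1	Telencephalon_L
14	IFG_orbitalis_R	6	IFG_R	2	Frontal_R	2	CerebralCortex_R	2	Telencephalon_R
15	IFG_triangularis_L	5	IFG_L	1	Frontal_L	1	CerebralCortex_L	1	Telencephalon_L
16	IFG_triangularis_R	6	IFG_R	2	Frontal_R	2	CerebralCortex_R	2	Telencephalon_R
17	LFOG_L	7	OG_L	1	Frontal_L	1	CerebralCortex_L	1	Telencephalon_L
18	LFOG_R	8	OG_R	2	Frontal_R	2	CerebralCortex_R	2	Telencephalon_R
19	MFOG_L	7	OG_L	1	Frontal_L	1	CerebralCortex_L	1	Telencephalon_L
20	MFOG_R	8	OG_R	2	Frontal_R	2	CerebralCortex_R	2	Telencephalon_R
21	RG_L	9	RG_L	1	Frontal_L	1	CerebralCortex_L	1	Telencephalon_L
22	RG_R	10	RG_R	2	Frontal_R	2	CerebralCortex_R	2	Telencephalon_R
23	PoCG_L	11	PoCG_L	3	Parietal_L	1	CerebralCortex_L	1	Telencephalon_L
24	PoCG_R	12	PoCG_R	4	Parietal_R	2	CerebralCortex_R	2	Telencephalon_R
25	PrCG_L	13	PrCG_L	1	Frontal_L	1	CerebralCortex_L	1	Telencephalon_L
26	PrCG_R	14	PrCG_R	2	Frontal_R	2	CerebralCortex_R	2	Telencephalon_R
27	SPG_L	15	SPG_L	3	Parietal_L	1	CerebralCortex_L	1	Telencephalon_L
28	SPG_R	16	SPG_R	4	Parietal_R	2	CerebralCortex_R	2	Telencephalon_R
29	SMG_L	17	SMG_L	3	Parietal_L	1	CerebralCortex_L	1	Telencephalon_L
30	SMG_R	18	SMG_R	4	Parietal_R	2	CerebralCortex_R	2	Telencephalon_R
31	AG_L	19	AG_L	3	Parietal_L	1	CerebralCortex_L	1	Telencephalon_L
32	AG_R	20	AG_R	4	Parietal_R	2	CerebralCortex_R	2	Telencephalon_R
33	PrCu_L	21	PrCu_L	3	Parietal_L	1	CerebralCortex_L	1	Telencephalon_L
34	PrCu_R	22	PrCu_R	4	Parietal_R	2	CerebralCortex_R	2	Telencephalon_R
35	STG_L	23	STG_L	5	Temporal_L	1	CerebralCortex_L	1	Telencephalon_L
36	STG_R	24	STG_R	6	Temporal_R	2	CerebralCortex_R	2	Telencephalon_R
37	STG_L_pole	23	STG_L	5	Temporal_L	1	CerebralCortex_L	1	Telencephalon_L
38	STG_R_pole	24	STG_R	6	Temporal_R	2	CerebralCortex_R	2	Telencephalon_R
39	MTG_L	25	MTG_L	5	Temporal_L	1	CerebralCortex_L	1	Telencephalon_L
40	MTG_R	26	MTG_R	6	Temporal_R	2	CerebralCortex_R	2	Telencephalon_R
41	MTG_L_pole	25	MTG_L	5	Temporal_L	1	CerebralCortex_L	1	Telencephalon_L
42	MTG_R_pole	26	MTG_R	6	Temporal_R	2	CerebralCortex_R	2	Telencephalon_R
43	ITG_L	27	ITG_L	5	Temporal_L	1	CerebralCortex_L	1	Telencephalon_L
44	ITG_R	28	ITG_R	6	Temporal_R	2	CerebralCortex_R	2	Telencephalon_R
45	PHG_L	29	Limbic_L	7	Limbic_L	1	CerebralCortex_L	1	Telencephalon_L
46	PHG_R	30	Limbic_R	8	Limbic_R	2	CerebralCortex_R	2	Telencephalon_R
47	ENT_L	29	Limbic_L	7	Limbic_L	1	CerebralCortex_L	1	Telencephalon_L
48	ENT_R	30	Limbic_R	8	Limbic_R	2	CerebralCortex_R	2	Telencephalon_R
49	FuG_L	31	FuG_L	5	Temporal_L	1	CerebralCortex_L	1	Telencephalon_L
50	FuG_R	32	FuG_R	6	Temporal_R	2	CerebralCortex_R	2	Telencephalon_R
51	SOG_L	33	SOG_L	9	Occipital_L	1	CerebralCortex_L	1	Telencephalon_L
52	SOG_R	34	SOG_R	10	Occipital_R	2	CerebralCortex_R	2	Telencephalon_R
53	MOG_L	35	MOG_L	9	Occipital_L	1	CerebralCortex_L	1	Telencephalon_L
54	MOG_R	36	MOG_R	10	Occipital_R	2	CerebralCortex_R	2	Telencephalon_R
55	IOG_L	37	IOG_L	9	Occipital_L	1	CerebralCortex_L	1	Telencephalon_L
56	IOG_R	38	IOG_R	10	Occipital_R	2	CerebralCortex_R	2	Telencephalon_R
57	Cu_L	39	Cu_L	9	Occipital_L	1	CerebralCortex_L	1	Telencephalon_L
58	Cu_R	40	Cu_R	10	Occipital_R	2	CerebralCortex_R	2	Telencephalon_R
59	LG_L	41	LG_L	9	Occipital_L	1	CerebralCortex_L	1	Telencephalon_L
60	LG_R	42	LG_R	10	Occipital_R	2	CerebralCortex_R	2	Telencephalon_R
61	rostral_L	43	Cingulate_L	7	Limbic_L	1	CerebralCortex_L	1	Telencephalon_L
62	rostral_R	44	Cingulate_R	8	Limbic_R	2	CerebralCortex_R	2	Telencephalon_R
63	subcallosal_L	43	Cingulate_L	7	Limbic_L	1	CerebralCortex_L	1	Telencephalon_L
64	subcallosal_R	44	Cingulate_R	8	Limbic_R	2	CerebralCortex_R	2	Telencephalon_R
65	subgenual_ACC_L	43	Cingulate_L	7	Limbic_L	1	CerebralCortex_L	1	Telencephalon_L
66	subgenual_ACC_R	44	Cingulate_R	8	Limbic_R	2	CerebralCortex_R	2	Telencephalon_R
67	dorsal_ACC_L	43	Cingulate_L	7	Limbic_L	1	CerebralCortex_L	1	Telencephalon_L
68	dorsal_ACC_R	44	Cingulate_R	8	Limbic_R	2	CerebralCortex_R	2	Telencephalon_R
69	PCC_L	43	Cingulate_L	7	Limbic_L	1	CerebralCortex_L	1	Telencephalon_L
70	PCC_R	44	Cingulate_R	8	Limbic_R	2	CerebralCortex_R	2	Telencephalon_R
71	Insula_L	45	Insula_L	11	Insula_L	1	CerebralCortex_L	1	Telencephalon_L
72	Insula_R	46	Insula_R	12	Insula_R	2	CerebralCortex_R	2	Telencephalon_R
73	Amyg_L	47	Amyg_L	7	Limbic_L	1	CerebralCortex_L	1	Telencephalon_L
74	Amyg_R	48	Amyg_R	8	Limbic_R	2	CerebralCortex_R	2	Telencephalon_R
75	Hippo_L	49	Hippo_L	7	Limbic_L	1	CerebralCortex_L	1	Telencephalon_L
76	Hippo_R	50	Hippo_R	8	Limbic_R	2	CerebralCortex_R	2	Telencephalon_R
77	Caud_L	51	Caud_L	13	BasslGang_L	3	CerebralNucli_L	1	Telencephalon_L
78	Caud_R	52	Caud_R	14	BasslGang_R	4	CerebralNucli_R	2	Telencephalon_R
79	Put_L	53	Put_L	13	BasslGang_L	3	CerebralNucli_L	1	Telencephalon_L
80	Put_R	54	Put_R	14	BasslGang_R	4	CerebralNucli_R	2	Telencephalon_R
81	GP_L	55	GP_L	13	BasslGang_L	3	CerebralNucli_L	1	Telencephalon_L
82	GP_R	56	GP_R	14	BasslGang_R	4	CerebralNucli_R	2	Telencephalon_R
83	Thalamus_L	57	Thalamus_L	15	Thalamus_L	5	Thalamus_L	3	Diencephalon_L
84	Thalamus_R	58	Thalamus_R	16	Thalamus_R	6	Thalamus_R	4	Diencephalon_R
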