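index	name	class	hemisphere
1	Precentral_L	cortical	left
2	Precentral_R	cortical	right
3	Frontal_Sup_L	cortical	left
4	Frontal_Sup_R	cortical	right
5	Frontal_Sup_Orb_L	cortical	left
6	Frontal_Sup_Orb_R	cortical	right
7	Frontal_Mid_L	cortical	left
8	Frontal_Mid_R	cortical	right
9	Frontal_Mid_Orb_L	cortical	left
10	Frontal_Mid_Orb_R	cortical	right
11	Frontal_Inf_Oper_L	cortical	left
12	Frontal_Inf_Oper_R	cortical	right
13	Frontal_Inf_Tri_L	cortical	left
14	Frontal_Inf_Tri_R	cortical	right
15	Frontal_Inf_Orb_L	cortical	left
16	Frontal_Inf_Orb_R	cortical	right
17	Rolandic_Oper_L	cortical	left
18	Rolandic_Oper_R	cortical	right
19	Supp_Motor_Area_L	cortical	left
20	Supp_Motor_Area_R	cortical	right
21	Olfactory_L	cortical	left
22	Olfactory_R	cortical	right
23	Frontal_Sup_Medial_L	cortical	left
24	Frontal_Sup_Medial_R	cortical	right
25	Frontal_Med_Orb_L	cortical	left
26	Frontal_Med_Orb_R	cortical	right
27	Rectus_L	cortical	left
28	Rectus_R	cortical	right
29	Insula_L	cortical	left
30	Insula_R	cortical	right
31	Cingulum_Ant_L	cortical	left
32	Cingulum_Ant_R	cortical	right
33	Cingulum_Mid_L	cortical	left
34	Cingulum_Mid_R	cortical	right
35	Cingulum_Post_L	cortical	left
36	Cingulum_Post_R	cortical	right
37	Hippocampus_L	cortical	left
38	Hippocampus_R	cortical	right
39	ParaHippocampal_L	cortical	left
40	ParaHippocampal_R	cortical	right
41	Amygdala_L	cortical	left
42	Amygdala_R	cortical	right
43	Calcarine_L	cortical	left
44	Calcarine_R	cortical	right
45	Cuneus_L	cortical	left
46	Cuneus_R	cortical	right
47	Lingual_L	cortical	left
48	Lingual_R	cortical	right
49	Occipital_Sup_L	cortical	left
50	Occipital_Sup_R	cortical	right
51	Occipital_Mid_L	cortical	left
52	Occipital_Mid_R	cortical	right
53	Occipital_Inf_L	cortical	left
54	Occipital_Inf_R	cortical	right
55	Fusiform_L	cortical	left
56	Fusiform_R	cortical	right
57	Postcentral_L	cortical	left
58	Postcentral_R	cortical	right
59	Parietal_Sup_L	cortical	left
60	Parietal_Sup_R	cortical	right
61	Parietal_Inf_L	cortical	left
62	Parietal_Inf_R	cortical	right
63	SupraMarginal_L	cortical	left
64	SupraMarginal_R	cortical	right
65	Angular_L	cortical	left
66	Angular_R	cortical	right
67	Precuneus_L	cortical	left
68	Precuneus_R	cortical	right
69	Paracentral_Lobule_L	cortical	left
70	Paracentral_Lobule_R	cortical	right
71	Caudate_L	cortical	left
72	Caudate_R	cortical	right
73	Putamen_L	cortical	left
74	Putamen_R	cortical	right
75	Pallidum_L	cortical	left
76	Pallidum_R	cortical	right
77	Thalamus_L	cortical	left
78	Thalamus_R	cortical	right
79	Heschl_L	cortical	left
80	Heschl_R	cortical	right
81	Temporal_Sup_L	cortical	left
82	Temporal_Sup_R	cortical	right
83	Temporal_Pole_Sup_L	cortical	left
84	Temporal_Pole_Sup_R	cortical	right
85	Temporal_Mid_L	cortical	left
86	Temporal_Mid_R	cortical	right
87	Temporal_Pole_Mid_L	cortical	left
88	Temporal_Pole_Mid_R	cortical	right
89	Temporal_Inf_L	cortical	left
90	Temporal_Inf_R	cortical	right
91	Cerebelum_Crus1_L	cerebellar	left
92	Cerebelum_Crus1_R	cerebellar	right
93	Cerebelum_Crus2_L	cerebellar	left
94	Cerebelum_Crus2_R	cerebellar	right
95	Cerebelum_3_L	cerebellar	left
96	Cerebelum_3_R	cerebellar	right
97	Cerebelum_4_5_L	cerebellar	left
98	Cerebelum_4_5_R	cerebellar	right
99	Cerebelum_6_L	cerebellar	left
100	Cerebelum_6_R	cerebellar	right
101	Cerebelum_7b_L	cerebellar	left
102	Cerebelum_7b_R	cerebellar	right
103	Cerebelum_8_L	cerebellar	left
104	Cerebelum_8_R	cerebellar	right
105	Cerebelum_9_L	cerebellar	left
106	Cerebelum_9_R	cerebellar	right
107	Cerebelum_10_L	cerebellar	left
108	Cerebelum_10_R	cerebellar	right
109	Vermis_1_2	vermis	midline
110	Vermis_3	vermis	midline
111	Vermis_4_5	vermis	midline
112	Vermis_6	vermis	midline
113	Vermis_7	vermis	midline
114	Vermis_8	vermis	midline
115	Vermis_9	vermis	midline
116	Vermis_10	vermis	midline
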