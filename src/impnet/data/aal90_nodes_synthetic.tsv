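node_id	label	volume_mm3
0	Precentral_L	10071.5
1	Precentral_R	4241.4
2	Frontal_Sup_L	5414.3
3	Frontal_Sup_R	11020.5
4	Frontal_Sup_Orb_L	7286.2
5	Frontal_Sup_Orb_R	7224.1
6	Frontal_Mid_L	12055.7
7	Frontal_Mid_R	4628.8
8	Frontal_Mid_Orb_L	2660.7
9	Frontal_Mid_Orb_R	14212.8
10	Frontal_Inf_Oper_L	5520.5
11	Frontal_Inf_Oper_R	15596.6
12	Frontal_Inf_Tri_L	27655.6
13	Frontal_Inf_Tri_R	13409.4
14	Frontal_Inf_Orb_L	10842.2
15	Frontal_Inf_Orb_R	5454.5
16	Rolandic_Oper_L	3412.2
17	Rolandic_Oper_R	6506.1
18	Supp_Motor_Area_L	15243.9
19	Supp_Motor_Area_R	5374.4
20	Olfactory_L	15256.0
21	Olfactory_R	10353.6
22	Frontal_Sup_Medial_L	6552.7
23	Frontal_Sup_Medial_R	10133.4
24	Frontal_Med_Orb_L	4225.9
25	Frontal_Med_Orb_R	4746.3
26	Rectus_L	11960.4
27	Rectus_R	6062.5
28	Insula_L	5935.4
29	Insula_R	18537.9
30	Cingulum_Ant_L	6478.5
31	Cingulum_Ant_R	8933.2
32	Cingulum_Mid_L	4920.9
33	Cingulum_Mid_R	16167.0
34	Cingulum_Post_L	5932.3
35	Cingulum_Post_R	9702.3
36	Hippocampus_L	11169.9
37	Hippocampus_R	18747.7
38	ParaHippocampal_L	3248.3
39	ParaHippocampal_R	7008.4
40	Amygdala_L	9110.7
41	Amygdala_R	5081.2
42	Calcarine_L	10646.5
43	Calcarine_R	3006.7
44	Cuneus_L	9210.2
45	Cuneus_R	7683.9
46	Lingual_L	6661.1
47	Lingual_R	5101.0
48	Occipital_Sup_L	9162.0
49	Occipital_Sup_R	4660.1
50	Occipital_Mid_L	16873.8
51	Occipital_Mid_R	16787.1
52	Occipital_Inf_L	9441.9
53	Occipital_Inf_R	8131.9
54	Fusiform_L	14032.2
55	Fusiform_R	3641.3
56	Postcentral_L	8055.4
57	Postcentral_R	12590.6
58	Parietal_Sup_L	8505.4
59	Parietal_Sup_R	15843.3
60	Parietal_Inf_L	5441.6
61	Parietal_Inf_R	5582.0
62	SupraMarginal_L	14924.7
63	SupraMarginal_R	2635.0
64	Angular_L	19079.6
65	Angular_R	9541.5
66	Precuneus_L	4766.2
67	Precuneus_R	8027.9
68	Paracentral_Lobule_L	6916.0
69	Paracentral_Lobule_R	7922.6
70	Caudate_L	6647.4
71	Caudate_R	9211.3
72	Putamen_L	6564.1
73	Putamen_R	6084.0
74	Pallidum_L	5334.4
75	Pallidum_R	4105.8
76	Thalamus_L	12075.2
77	Thalamus_R	10387.6
78	Heschl_L	7655.9
79	Heschl_R	5717.2
80	Temporal_Sup_L	4319.7
81	Temporal_Sup_R	7219.2
82	Temporal_Pole_Sup_L	22733.0
83	Temporal_Pole_Sup_R	11095.9
84	Temporal_Mid_L	38818.6
85	Temporal_Mid_R	14221.1
86	Temporal_Pole_Mid_L	10639.2
87	Temporal_Pole_Mid_R	8076.8
88	Temporal_Inf_L	10576.5
89	Temporal_Inf_R	7640.2
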