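no	feature_id	rt_seconds	mz	ion_mode	ratio_vs_b313	p_value	vip	strain	compound	cas
1	M190T192	192	190	positive	84.57	1.50E-05	2.51	B108	Kynurenic acid	492-27-3
2	M115T124	124	115	positive	116.47	4.55E-08	3.02	B253	Ethylmalonic acid	601-75-2
3	M131T125	125	131	negative	272.19	2.05E-09	3.82	B253	Glutaric acid	110-94-1
4	M145T115	115	145	negative	35.59	6.98E-13	3.08	B253	Adipic acid	124-04-9
5	M125T103	103	125	negative	16.01	9.73E-07	2.27	B253	Thymine	65-71-4
6	M124T65	65	124	positive	1552.84	4.14E-06	6.40	B263	Picolinic acid	98-98-6
7	M124T82	82	124	positive	546.33	5.32E-09	5.57	B263	Picolinic acid	98-98-6
8	M137T63	63	137	positive	96.63	1.00E-10	4.74	B263	Hypoxanthine	68-94-0
9	M115T124	124	115	positive	79.63	7.77E-08	4.69	B263	Ethylmalonic acid	601-75-2
10	M176T307	307	176	positive	54.29	6.79E-17	3.65	B263	Indoleacetic acid	87-51-4
11	M137T84	84	137	positive	40.63	4.43E-07	3.83	B263	Hypoxanthine	68-94-0
12	M135T84	84	135	negative	379.16	1.45E-07	5.41	B263	Hypoxanthine	68-94-0
13	M131T125	125	131	negative	211.67	5.44E-09	4.61	B263	Glutaric acid	110-94-1
14	M145T115	115	145	negative	27.01	1.04E-11	3.58	B263	Adipic acid	124-04-9
15	M125T103	103	125	negative	17.56	3.51E-06	2.97	B263	Thymine	65-71-4
16	M124T65	65	124	positive	1834.90	3.82E-06	6.00	B505	Picolinic acid	98-98-6
17	M137T63	63	137	positive	102.63	1.31E-10	4.41	B505	Hypoxanthine	68-94-0
18	M190T192	192	190	positive	40.13	3.30E-05	3.49	B505	Kynurenic acid	492-27-3
19	M137T84	84	137	positive	39.37	1.87E-07	3.54	B505	Hypoxanthine	68-94-0
20	M135T84	84	135	negative	385.13	1.33E-07	4.96	B505	Hypoxanthine	68-94-0
21	M131T125	125	131	negative	26.74	2.47E-08	2.59	B505	Glutaric acid	110-94-1
22	M125T103	103	125	negative	18.24	2.13E-06	2.75	B505	Thymine	65-71-4
23	M145T115	115	145	negative	12.45	2.34E-11	2.51	B505	Adipic acid	124-04-9
24	M115T124	124	115	positive	99.99	9.33E-09	2.83	B585	Ethylmalonic acid	601-75-2
25	M131T125	125	131	negative	233.92	6.66E-10	3.67	B585	Glutaric acid	110-94-1
26	M145T115	115	145	negative	40.09	9.46E-13	3.14	B585	Adipic acid	124-04-9
27	M125T103	103	125	negative	14.71	2.48E-06	2.18	B585	Thymine	65-71-4
28	M124T226	226	124	positive	270.36	1.01E-06	4.35	B424	Picolinic acid	98-98-6
29	M129T65	65	129	negative	35.08	2.01E-06	3.70	B424	Ketoisocaproic acid	816-66-0
30	M129T41	41	129	negative	18.13	8.04E-05	3.36	B424	Ketoisocaproic acid	816-66-0
31	M165T154	154	165	negative	15.91	8.20E-07	3.22	B424	Phenyllactic acid	828-01-3
32	M165T106	106	165	negative	12.30	5.67E-12	3.08	B424	Phenyllactic acid	828-01-3
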