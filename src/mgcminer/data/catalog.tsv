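organism	phylum_class	accession	size_bp	n_scaffolds	gc_percent	n50_bp	completeness	contamination	genome_type	source_table
Magnetovibrio sp. ARS8	Alphaproteobacteria	GCA_002686765.1	2019305	197	59.64	10605	62.87	1.00	genome	1
Elusimicrobia bacterium NORP122	Elusimicrobia	GCA_002401485.1	2913226	191	54.93	19622	74.06	1.82	genome	1
Unclassified Nitrospina Bin 25	Nitrospinae	2651870060	4158979	431	37.69	11956	92.31	4.27	genome	1
Planctomycetes bacterium SCGC_JGI090-P21	Planctomycetes	2264265205	1230646	242	49.20	12722	38.87	2.19	genome	1
Ca. Hydrogenedentes bacterium MAG_17963_hgd_111	Ca. Hydrogenedentes	3300017963	3018788	288	60.18	11662	71.11	1.46	MAG	2
Ca. Hydrogenedentes bacterium MAG_17971_hgd_130	Ca. Hydrogenedentes	3300017971	2683901	240	60.43	12541	60.01	1.16	MAG	2
Deltaproteobacteria bacterium MAG_00134_naph_006	Deltaproteobacteria	3300000134	1498667	692	49.54	2676	60.69	3.87	MAG	2
Deltaproteobacteria bacterium MAG_00241_naph_010	Deltaproteobacteria	3300000241	1547003	324	49.45	6761	55.59	2.41	MAG	2
Deltaproteobacteria bacterium MAG_00792_naph_016	Deltaproteobacteria	3300000792	3032840	409	49.74	11269	89.28	5.86	MAG	2
Deltaproteobacteria bacterium MAG_09788_naph_37	Deltaproteobacteria	3300009788	899797	137	47.24	7579	49.08	0.97	MAG	2
Deltaproteobacteria bacterium MAG_15370_dsfb_81	Deltaproteobacteria	3300015370	3868622	334	48.42	14397	89.68	5.59	MAG	2
Deltaproteobacteria bacterium MAG_17929_sntb_26	Deltaproteobacteria	3300017929	2777907	276	53.10	17193	62.13	5.10	MAG	2
Deltaproteobacteria bacterium MAG_17996_sntb_20	Deltaproteobacteria	3300017996	1691080	454	53.11	4033	50.53	2.33	MAG	2
Deltaproteobacteria bacterium MAG_22204_dsfv_001	Deltaproteobacteria	3300022204	2675335	75	52.74	60141	89.52	0.36	MAG	2
Deltaproteobacteria bacterium MAG_22309_dsfv_022	Deltaproteobacteria	3300022309	2902378	66	55.15	78905	91.60	1.79	MAG	2
Gammaproteobacteria bacterium MAG_00150_gam_010	Gammaproteobacteria	3300000150	2847655	486	49.07	8986	98.17	3.96	MAG	2
Gammaproteobacteria bacterium MAG_00160_gam_009	Gammaproteobacteria	3300000160	2903803	318	49.10	15339	99.39	4.88	MAG	2
Gammaproteobacteria bacterium MAG_00172_gam_018	Gammaproteobacteria	3300000172	2866084	274	48.97	18904	96.95	3.05	MAG	2
Gammaproteobacteria bacterium MAG_00188_gam_006	Gammaproteobacteria	3300000188	2672010	567	48.83	6818	95.12	4.19	MAG	2
Gammaproteobacteria bacterium MAG_00212_gam_1	Gammaproteobacteria	3300000212	2103212	955	48.40	2901	78.43	5.08	MAG	2
Gammaproteobacteria bacterium MAG_00215_gam_020	Gammaproteobacteria	3300000215	2931288	507	49.02	8845	95.73	5.34	MAG	2
Magnetococcales bacterium MAG_21055_mgc_1	Ca. Etaproteobacteria	3300021055	3585593	930	52.41	5203	84.82	3.65	MAG	2
Nitrospinae bacterium MAG_09705_ntspn_70	Nitrospinae	3300009705	2024644	120	42.63	30902	67.25	2.56	MAG	2
Nitrospirae bacterium MAG_10313_ntr_31	Nitrospirae	3300010313	1933163	344	35.33	7568	90.20	3.64	MAG	2
Pelobacteraceae bacterium MAG_21601_9_030	Deltaproteobacteria	3300021601	2536371	232	54.11	20074	78.15	8.39	MAG	2
Pelobacteraceae bacterium MAG_13126_9_058	Deltaproteobacteria	3300013126	3576562	72	52.01	83631	91.61	1.29	MAG	2
Pelobacteraceae bacterium MAG_21600_9_004	Deltaproteobacteria	3300021600	3430740	60	51.50	87025	90.32	0.65	MAG	2
Planctomycetes bacterium MAG_11118_pl_115	Planctomycetes	3300011118	3767441	157	48.98	33372	89.44	1.24	MAG	2
Planctomycetes bacterium MAG_17991_pl_60	Planctomycetes	3300017991	1289005	144	49.53	10179	64.20	0.00	MAG	2
Planctomycetes bacterium MAG_18080_pl_157	Planctomycetes	3300018080	3144921	139	48.44	34208	90.91	3.41	MAG	2
Rhodospirillaceae bacterium MAG_01419_mvb_30	Alphaproteobacteria	3300001419	2811682	477	55.72	7268	94.58	4.10	MAG	2
Rhodospirillaceae bacterium MAG_04806_tlms_2	Alphaproteobacteria	3300004806	2085124	309	57.51	8435	87.64	2.12	MAG	2
Rhodospirillaceae bacterium MAG_05422_2-02_14	Alphaproteobacteria	3300005422	2281835	255	61.09	11800	85.45	0.50	MAG	2
Rhodospirillaceae bacterium MAG_05596_2-02_51	Alphaproteobacteria	3300005596	1831947	329	61.19	6777	76.91	0.25	MAG	2
Rhodospirillaceae bacterium MAG_06104_tlms_034	Alphaproteobacteria	3300006104	3186839	353	64.25	13005	89.59	2.53	MAG	2
Rhodospirillaceae bacterium MAG_22225_2-02_112	Alphaproteobacteria	3300022225	2547095	147	61.01	26510	91.17	5.22	MAG	2
Ca. Omnitrophica bacterium SCGC AG-290-C17 (SAG)	Ca. Omnitrophica	3300015153	1712617	171	48.60	13921	62.84	0.00	SAG	2
Uncultured microorganism SbSrfc.SA12.01.D19 (SAG)	Deltaproteobacteria	3300022116	2501480	175	52.60	25257	49.13	0.00	SAG	2
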