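name	pubmed_id	source_class	clinical_derived	n_genes_original	n_genes_final	tissue
Koong 2000	10706099	in_vitro	0	10	10	pharynx/cervix
Denko 2003	12947397	in_vitro	0	80	72	cervix
Jogi 2004	15093745	in_vitro	0	107	103	brain (neuroblastoma)
Ning 2004	15100389	in_vitro	0	104	99	aortic endothelial cells
Manalo 2005	15374877	in_vitro	0	107	105	coronary artery endothelial cells
Wang 2005	15833863	in_vitro	0	56	55	kidney
Detwiller 2005	15994966	in_vitro	0	27	27	fibrosarcoma/fibroblast/pancreas/kidney
Chi 2006	16417408	in_vitro	0	111	111	endothelial/smooth muscle/epithelial cells
Mense 2006	16507782	in_vitro	0	111	94	fetal astrocytes
Elvidge 2006	16565084	in_vitro	0	181	173	breast
Peters 2006	16595741	in_vitro	0	159	158	pulmonary artery endothelial cells
Aprelikova 2006	16740701	in_vitro	0	236	230	breast
Bosco 2006	16849508	in_vitro	0	177	173	peripheral blood monocytes
Shi 2007	17187782	in_vitro	0	32	31	hepatic stellate cells
Sung 2007	17320280	in_vitro	0	90	90	head and neck (nasopharyngeal carcinoma)
Winter 2007	17409455	clinical	1	99	97	head and neck (squamous cell carcinoma)
Seigneuric 2007 (common)	17532074	in_vitro	0	14	14	mammary epithelial cells
Seigneuric 2007 (early0)	17532074	in_vitro	0	71	68	mammary epithelial cells
Seigneuric 2007 (early2)	17532074	in_vitro	0	34	31	mammary epithelial cells
Beyer 2008	18984585	in_vitro	0	159	158	cervix/kidney/renal cancer
Hu 2009	19291283	clinical	1	13	13	breast
Benita 2009	19491311	in_vitro	0	57	54	colorectal/colon/pancreas/cervix/breast
Fardin 2009	19832978	in_vitro	0	8	8	brain (neuroblastoma)
Lendahl 2009	19884889	in_vitro	0	23	23	multiple
Buffa 2010	20087356	both	1	51	51	head and neck/breast
Ghorbel 2010	20416888	clinical	1	166	158	cyanotic tetralogy of Fallot
Sorensen 2010	20429727	in_vitro	0	27	26	cervix/head and neck
van Malenstein 2010	20592013	in_vitro	0	4	4	liver
Fardin 2010	20652058	in_vitro	0	35	35	brain (neuroblastoma)
Ghazoui 2011	21325071	clinical	1	70	68	breast
Toustrup 2011	21846821	in_vitro	0	15	15	head and neck/cervix
Starmans 2012	22356756	in_vitro	0	759	756	prostate/colon/breast
Halle 2012	22890239	both	1	31	31	cervix
Eustace 2013	23820108	clinical	1	26	25	laryngeal/bladder cancer
Boidot 2014 (continuous hypoxia)	25216520	both	1	98	93	multiple
Boidot 2014 (cyclic hypoxia)	25216520	both	1	96	90	multiple
Ragnum 2015	25461803	both	1	32	32	prostate
Fjeldbo 2016	27012812	clinical	1	6	6	cervix
Suh 2017	28324887	clinical	1	21	21	head and neck
Yang 2017	28400426	clinical	1	24	24	bladder
Ye 2018	30037853	in_vitro	0	42	42	breast
Yang 2018 (prostate)	29729848	both	1	28	28	prostate
Yang 2018 (sarcoma)	29423096	both	1	24	24	soft tissue sarcoma
Trong 2018	30257451	in_vitro	0	5	5	brain (glioma)
Chen 2019	30973670	in_vitro	0	17	17	lung (adenocarcinoma)
Zou 2019	31572060	clinical	1	14	14	colorectal
Zhang 2020	32887635	both	1	3	3	liver
Wang 2020	32724434	clinical	1	14	14	breast
Shou 2020	33133157	clinical	1	7	7	skin (melanoma)
Lin 2020	32500034	clinical	1	5	5	brain (glioma)
Mo 2020	32655624	clinical	1	4	4	lung (adenocarcinoma)
Sun 2020	32655701	clinical	1	16	16	lung (adenocarcinoma)
Tardon 2020	32887267	in_vitro	0	19	19	brain (glioblastoma multiforme)
Santamaria 2022	35641902	both	1	16	16	pan-cancer
Wang 2022	35155681	clinical	1	23	23	glioblastoma multiforme
Lane 2022	35079065	in_vitro	0	28	28	lung
Gao 2021	34868920	clinical	1	7	7	glioma
Khouzam 2021	34093582	in_vitro	0	8	8	multiple
Shou 2021	33624645	clinical	1	4	4	melanoma
Zhang 2021	33616276	in_vitro	0	21	21	liver
Shi 2021	33754044	clinical	1	10	10	lung (adenocarcinoma)
Liu 2022	35769999	clinical	1	6	6	cervical cancer
Xu 2022	35734431	clinical	1	3	3	colon
Wei 2021	34950205	clinical	1	8	8	ovarian
He 2021	34938106	clinical	1	4	4	colon
Xia 2021	34722497	both	1	7	7	prostate
Sun 2021	34490098	both	1	3	3	triple-negative breast cancer
Li 2021	34194464	clinical	1	8	8	liver
Zhao 2021	33941139	clinical	1	4	4	oral squamous cell carcinoma
Lombardi 2022	36384128	in_vitro	0	48	48	pan-cancer
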