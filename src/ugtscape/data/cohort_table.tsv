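cohort	description	n_tumors	total_mutations	n_tumors_with_ugt	total_ugt_mutations	n_missense_frameshift_nonsense	printed_mutations_per_tumor	printed_fraction_with_ugt
ACC	Adrenocortical Carcinoma	92	11981	9	14	8	130	0.097
BLCA	Bladder Urothelial Carcinoma	411	155233	102	145	90	377	0.248
BRCA	Breast Invasive Carcinoma	1019	135026	86	125	78	132	0.084
CESC	Cervical Squamous Cell Carcinoma and Endocervical Adenocarcinoma	289	83232	48	71	47	288	0.168
CHOL	Cholangiocarcinoma	36	4500	3	3	3	125	0.083
COAD	Colon Adenocarcinoma	402	242404	102	218	159	602	0.253
DLBC	Lymphoid Neoplasm Diffuse Large B-cell Lymphoma	37	7784	5	5	3	210	0.142
ESCA	Esophageal Carcinoma	183	48196	27	31	20	263	0.147
GBM	Glioblastoma Multiforme	380	40617	82	96	66	106	0.215
HNSC	Head and Neck Squamous Cell Carcinoma	507	125417	106	147	83	247	0.209
KICH	Kidney Chromophobe	66	3324	4	4	3	50	0.060
KIRC	Kidney Renal Clear Cell Carcinoma	371	32001	25	28	20	86	0.067
KIRP	Kidney Renal Papillary Cell Carcinoma	281	35445	32	33	24	126	0.113
LAML	Acute Myeloid Leukemia	140	8332	6	10	5	59	0.042
LGG	Brain Lower Grade Glioma	512	24000	34	37	30	46	0.066
LIHC	Liver Hepatocellular Carcinoma	363	60432	45	50	32	166	0.123
LUAD	Lung Adenocarcinoma	512	243687	235	412	287	475	0.458
LUSC	Lung Squamous Cell Carcinoma	484	204623	166	253	182	422	0.342
MESO	Mesothelioma	82	3979	1	1	1	48	0.012
OV	Ovary Serous Cystadenocarcinoma	406	53115	60	71	44	130	0.147
PCPG	Pheochromocytoma and Paraganglioma	179	2726	4	4	1	15	0.022
PAAD	Pancreatic Adenocarcinoma	155	8728	3	3	2	56	0.019
PRAD	Prostate Adenocarcinoma	495	24778	19	22	15	50	0.038
READ	Rectum Adenocarcinoma	146	30380	19	26	18	208	0.130
SARC	Sarcoma	236	31678	33	41	26	134	0.139
SKCM-primary	Skin Cutaneous Melanoma (primary)	103	68991	56	160	94	669	0.543
SKCM-metastatic	Skin Cutaneous Melanoma (Metastatic)	364	438405	246	926	592	1204	0.675
STAD	Stomach Adenocarcinoma	437	221714	105	175	120	507	0.240
TGCT	Testicular Germ Cell Tumor	144	3588	0	0	0	24	0.000
THCA	Thyroid Carcinoma	491	12050	9	10	8	24	0.018
THYM	Thymoma	122	4888	2	3	2	40	0.016
UCEC	Uterine Corpus Endometrial Carcinoma	487	307642	122	297	193	631	0.250
UCS	Uterine Carcinoma	57	5261	5	5	3	92	0.087
UVM	Uveal Melanoma	80	1935	1	1	1	24	0.012
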