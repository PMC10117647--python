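code	name	source	SQ	r1	rS1	rS	dS	log10_mu1	log10_muS1	log10_muS	log10_muI	p_value
ACC	Adrenocortical Carcinoma	TCGA, PanCancer Atlas	0.616	1.003	0.958	5.578	3.436	-3.212	-3.979	-3.006	-10.197	0.9120
BLCA	Bladder Urothelial Carcinoma	TCGA, PanCancer Atlas	0.922	1.097	0.981	5.614	3.939	-2.876	-3.616	-3.223	-9.715	0.8857
BRCA	Breast Invasive Carcinoma	TCGA, PanCancer Atlas	0.983	0.945	0.948	2.967	1.887	-3.770	-2.228	-2.661	-8.658	0.1707
CESC	Cervical Squamous Cell Carcinoma	TCGA, PanCancer Atlas	0.897	0.929	0.951	6.684	3.506	-3.842	-3.233	-2.098	-9.172	0.1213
CHOL	Cholangiocarcinoma	TCGA, PanCancer Atlas	0.847	0.988	1.011	7.170	3.765	-3.504	-2.759	-2.349	-8.612	0.7716
COAD	Colorectal Adenocarcinoma	TCGA, PanCancer Atlas	0.943	1.086	1.027	5.912	3.859	-3.176	-3.052	-4.347	-10.575	0.2783
ESCA	Esophageal Adenocarcinoma	TCGA, PanCancer Atlas	0.936	1.048	0.919	6.767	3.655	-4.114	-3.870	-2.411	-10.394	0.8862
HNSC	Head & Neck Squamous Cell Carcinoma	TCGA, PanCancer Atlas	0.802	0.980	0.988	5.148	3.586	-2.735	-4.886	-2.656	-10.277	0.5908
KICH	Kidney Chromophobe	TCGA, PanCancer Atlas	0.401	1.070	1.024	2.308	1.558	-3.971	-2.542	-4.658	-11.170	0.9360
KIRC	Kidney Renal Clear Cell Carcinoma	TCGA, PanCancer Atlas	0.786	1.081	1.064	3.655	2.713	-4.569	-3.445	-4.252	-12.265	0.1519
KIRP	Kidney Renal Papillary Cell Carcinoma	TCGA, PanCancer Atlas	0.559	0.965	0.958	5.470	3.004	-3.182	-2.748	-3.374	-9.304	0.9880
LIHC	Liver Hepatocellular Carcinoma	TCGA, PanCancer Atlas	0.846	0.977	1.009	7.675	3.899	-4.620	-3.690	-4.252	-12.562	0.6744
LUAD	Lung Adenocarcinoma	TCGA, PanCancer Atlas	0.600	0.922	0.977	6.383	3.327	-3.068	-3.471	-2.821	-9.360	0.4484
LUSC	Lung Squamous Cell Carcinoma	TCGA, PanCancer Atlas	0.524	0.997	0.952	5.220	3.568	-4.174	-2.276	-3.258	-9.708	0.9767
MESO	Mesothelioma	TCGA, PanCancer Atlas	0.572	0.918	1.030	7.134	3.581	-3.287	-4.222	-3.561	-11.070	0.8411
OV	Ovarian Serous Cystadenocarcinoma	TCGA, PanCancer Atlas	0.772	1.052	0.939	4.145	2.655	-3.483	-2.415	-3.502	-9.400	0.9710
PAAD	Pancreatic Adenocarcinoma	TCGA, PanCancer Atlas	0.736	0.988	0.996	3.145	1.654	-3.218	-2.875	-2.416	-8.509	0.8931
PRAD	Prostate Adenocarcinoma	TCGA, PanCancer Atlas	0.886	0.915	0.918	4.826	3.584	-2.286	-3.987	-2.189	-8.462	0.7336
STAD	Stomach Adenocarcinoma	TCGA, PanCancer Atlas	0.400	0.936	0.949	5.738	3.177	-3.377	-2.268	-3.389	-9.034	0.9442
SKCM	Skin Cutaneous Melanoma	TCGA, Firehose Legacy	0.805	1.016	0.980	2.848	1.818	-4.481	-3.607	-2.512	-10.601	0.5770
THCA	Thyroid Carcinoma	TCGA, PanCancer Atlas	0.764	1.020	0.980	6.541	3.525	-2.824	-4.268	-4.131	-11.222	0.7340
UCEC	Uterine Corpus Endometrial Carcinoma	TCGA, PanCancer Atlas	0.892	0.948	0.984	3.965	2.083	-4.276	-3.824	-2.908	-11.007	0.1153
UVM	Uveal Melanoma	TCGA, Firehose Legacy	0.564	1.022	0.947	6.612	3.535	-3.397	-2.166	-4.000	-9.563	0.2663
ACYC	Adenoid Cystic Carcinoma	MSK, Nat Genet 2013	0.521	1.082	1.065	4.523	2.492	-2.754	-3.342	-4.046	-10.142	0.6316
MEL	Acral Melanoma	TGEN, Genome Res 2017	0.524	1.031	1.008	5.199	3.104	-2.572	-3.866	-2.487	-8.925	0.3385
OSCC	Oral Squamous Cell Carcinoma	MD Anderson, Canc. Disc 2013	1.033	0.901	0.990	8.090	3.700	-2.721	-2.602	-3.640	-8.964	0.9997
UTUC	Upper Tract Urothelial Cancer	MSK, Eur Urol 2015	0.628	0.938	1.009	7.470	3.800	-2.130	-3.672	-2.815	-8.617	0.5480
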