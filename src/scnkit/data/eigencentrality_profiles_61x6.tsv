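cluster	region	average	HC-BD	MDD-BD	MDD-HC	SCH-BD	SCH-HC	SCH-MDD
1	SMG supramarginal	0.0386	0.0366	0.0375	0.0274	0.0413	0.0468	0.0421
1	AOrG ant orbital	0.0333	0.0164	0.0164	0.0476	0.0164	0.0578	0.0451
1	PO parietal operculum	0.0294	0.0214	0.0050	0.0233	0.0445	0.0478	0.0343
1	Cun cuneus	0.0258	0.0128	0.0208	0.0004	0.0422	0.0528	0.0255
1	Hippocampus	0.0251	0.0210	0.0097	0.0004	0.0543	0.0440	0.0212
1	SPL sup parietal	0.0239	0.0139	0.0083	0.0049	0.0386	0.0528	0.0245
1	Calc calcarine	0.0224	0.0123	0.0058	0.0005	0.0395	0.0528	0.0232
1	LOrG lateral orbital	0.0218	0.0302	0.0010	0.0211	0.0382	0.0374	0.0028
1	PrG precentral	0.0210	0.0164	0.0164	0.0112	0.0164	0.0416	0.0243
2	PoG postcentral	0.0400	0.0154	0.0614	0.0361	0.0405	0.0416	0.0451
2	SCA subcallosal area	0.0379	0.0543	0.0346	0.0480	0.0343	0.0182	0.0380
2	PHG parahippocampal	0.0291	0.0431	0.0405	0.0404	0.0092	0.0149	0.0263
2	CO central operculum	0.0276	0.0255	0.0319	0.0324	0.0252	0.0164	0.0345
2	TrIFG triangular inf front	0.0229	0.0006	0.0589	0.0345	0.0038	0.0048	0.0348
3	MFG mid front	0.0128	0.0288	0.0116	0.0036	0.0220	0.0026	0.0080
3	MPoG postcentral medial	0.0126	0.0221	0.0204	0.0042	0.0175	0.0070	0.0047
3	POrG post orbital	0.0113	0.0164	0.0164	0.0164	0.0069	0.0058	0.0061
3	FO front operculum	0.0113	0.0164	0.0174	0.0164	0.0018	0.0029	0.0131
3	MFC medial front	0.0111	0.0009	0.0292	0.0121	0.0118	0.0067	0.0061
3	Pallidum	0.0105	0.0164	0.0164	0.0164	0.0050	0.0048	0.0038
3	PT planum temporale	0.0104	0.0164	0.0241	0.0089	0.0037	0.0001	0.0091
3	AnG angular	0.0088	0.0095	0.0060	0.0164	0.0038	0.0007	0.0164
3	Caudate	0.0086	0.0164	0.0164	0.0016	0.0164	0.0002	0.0004
3	OrIFG orbital inf front	0.0085	0.0079	0.0132	0.0164	0.0081	0.0051	0.0003
3	PIns post insula	0.0083	0.0086	0.0051	0.0164	0.0170	0.0021	0.0004
3	AIns ant insula	0.0081	0.0164	0.0016	0.0085	0.0045	0.0164	0.0010
3	PCu precuneus	0.0078	0.0024	0.0121	0.0164	0.0049	0.0074	0.0036
3	MSFG sup front medial	0.0070	0.0076	0.0081	0.0004	0.0153	0.0061	0.0043
3	SMC supp motor	0.0064	0.0155	0.0088	0.0000	0.0104	0.0013	0.0021
3	Thalamus Proper	0.0057	0.0041	0.0144	0.0026	0.0036	0.0056	0.0041
3	SFG sup front	0.0056	0.0045	0.0058	0.0010	0.0141	0.0026	0.0054
3	MTG mid temporal	0.0048	0.0041	0.0064	0.0024	0.0053	0.0035	0.0071
4	TMP temporal pole	0.0223	0.0164	0.0164	0.0365	0.0164	0.0172	0.0310
4	STG sup temporal	0.0198	0.0164	0.0164	0.0370	0.0164	0.0021	0.0305
4	PP planum polare	0.0190	0.0164	0.0164	0.0319	0.0164	0.0164	0.0164
4	OpIFG opercular inf front	0.0182	0.0175	0.0185	0.0290	0.0141	0.0108	0.0193
4	FRP front pole	0.0167	0.0164	0.0164	0.0184	0.0164	0.0164	0.0164
4	MOrG medial orbital	0.0165	0.0164	0.0164	0.0171	0.0164	0.0164	0.0164
4	Basal Forebrain	0.0164	0.0164	0.0164	0.0164	0.0164	0.0164	0.0164
4	CerebVermal I0x2DV	0.0164	0.0164	0.0164	0.0164	0.0164	0.0164	0.0164
4	Cerebellum Exterior	0.0164	0.0164	0.0164	0.0164	0.0164	0.0164	0.0164
4	OCP occipital pole	0.0164	0.0164	0.0164	0.0164	0.0164	0.0164	0.0164
4	IOG inf occipital	0.0158	0.0187	0.0082	0.0164	0.0185	0.0164	0.0164
4	Ent entorhinal area	0.0157	0.0302	0.0164	0.0171	0.0086	0.0182	0.0034
4	MCgG mid cingulate	0.0153	0.0158	0.0032	0.0154	0.0304	0.0000	0.0271
4	GRe rectus	0.0153	0.0164	0.0275	0.0261	0.0035	0.0001	0.0182
4	SOG sup occipital	0.0146	0.0164	0.0164	0.0031	0.0164	0.0245	0.0107
4	Amygdala	0.0144	0.0349	0.0144	0.0121	0.0055	0.0168	0.0027
4	FuG fusiform	0.0143	0.0041	0.0164	0.0164	0.0164	0.0164	0.0164
4	TTG transverse temporal	0.0143	0.0164	0.0332	0.0154	0.0004	0.0008	0.0197
4	Cereb Vermal VIII DX	0.0138	0.0164	0.0164	0.0164	0.0164	0.0164	0.0010
4	Vermal VI0 DVII	0.0138	0.0164	0.0164	0.0164	0.0008	0.0164	0.0164
4	Accumbens Area	0.0137	0.0164	0.0164	0.0000	0.0164	0.0164	0.0164
4	ITG inf temporal	0.0136	0.0156	0.0104	0.0164	0.0211	0.0019	0.0164
4	LiG lingual	0.0136	0.0164	0.0164	0.0164	0.0140	0.0019	0.0164
4	ACgG ant cingulate	0.0134	0.0239	0.0028	0.0164	0.0047	0.0164	0.0164
4	MOG mid occipital	0.0132	0.0101	0.0179	0.0031	0.0119	0.0257	0.0108
4	Putamen	0.0129	0.0101	0.0164	0.0085	0.0086	0.0176	0.0164
4	uG occipital fusiform	0.0125	0.0164	0.0024	0.0164	0.0070	0.0164	0.0164
4	PCgG post cingulate	0.0117	0.0018	0.0012	0.0277	0.0048	0.0056	0.0289
4	MPrG precentral medial	0.0116	0.0041	0.0002	0.0164	0.0164	0.0164	0.0164
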