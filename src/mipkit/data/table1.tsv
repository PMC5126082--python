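subfamily	proposed_name	locus_id	chromosome	start	end	pI	MW	GRAVY	subcellular
PIP	CaPIP1-1	Ca_02435	Ca8	1717936	1719735	9.1	30.75	0.396	plas
PIP	CaPIP1-2	Ca_05754	Ca6	5464092	5465462	9	30.81	0.427	plas
PIP	CaPIP1-3	Ca_10319	Ca6	1932039	1933176	8.68	30.92	0.398	plas
PIP	CaPIP1-4	Ca_12502	Ca2	30479427	30481282	8.7	31.06	0.393	plas
PIP	CaPIP2-5	Ca_04707	Ca5	30303896	30304911	9.14	30.21	0.49	cyto
PIP	CaPIP2-1	Ca_08491	Ca4	10225765	10228793	8.34	30.52	0.588	plas
PIP	CaPIP2-2	Ca_12039	Ca3	32991462	32992568	9.11	30.8	0.406	plas
PIP	CaPIP2-3	Ca_14568	Ca6	27966413	27967838	6.71	30.58	0.375	plas
PIP	CaPIP2-4	Ca_02533	Ca1	12226605	12227713	7.81	30.87	0.382	plas
TIP	CaTIP1-1	Ca_00723	Ca3	34451205	34452295	6.02	25.47	0.88	vacu
TIP	CaTIP1-2	Ca_16712	Ca6	26818668	26820154	5.43	25.82	0.847	vacu
TIP	CaTIP1-3	Ca_18630	Ca4	17906721	17908388	5.61	26.01	0.78	plas
TIP	CaTIP1-4	Ca_19377	Ca3	11393179	11394299	4.94	25.79	0.744	cyto
TIP	CaTIP2-1	Ca_02797	Ca1	9896268	9897261	6.29	25.42	0.745	nucl
TIP	CaTIP2-2	Ca_24137	scaffold1844	60282	61675	5.3	25.32	0.873	vacu
TIP	CaTIP2-3	Ca_02338	Ca8	2481906	2483425	4.8	25.22	0.947	vacu
TIP	CaTIP3-1	Ca_03854	Ca4	3990175	3991038	7.31	27.59	0.565	cyto
TIP	CaTIP3-2	Ca_19737	Ca8	10865608	10867961	6.36	26.92	0.671	mito
TIP	CaTIP4-1	Ca_14915	Ca4	39954258	39957667	7.92	23.85	0.893	cyto
TIP	CaTIP4-2	Ca_14916	Ca4	39950985	39952627	5.51	25.87	0.777	vacu
TIP	CaTIP5-1	Ca_15805	Ca6	34791986	34793660	7.08	26.49	0.731	vacu
NIP	CaNIP1-1	Ca_06493	Ca6	18836478	18837512	5.15	26.59	0.732	plas
NIP	CaNIP1-2	Ca_16129	Ca2	29576437	29578961	7.06	28.53	0.632	plas
NIP	CaNIP1-3	Ca_08631	Ca6	9654827	9656732	8	28.67	0.522	vacu
NIP	CaNIP1-4	Ca_08632	Ca6	9651625	9653530	8	28.67	0.522	vacu
NIP	CaNIP1-5	Ca_08630	Ca6	9661095	9662900	9.15	29.44	0.504	cyto
NIP	CaNIP1-6	Ca_00434	Ca1	3567423	3568768	6.46	27.09	0.761	plas
NIP	CaNIP1-7	Ca_00435	Ca1	3574718	3576622	8.98	29.17	0.421	plas
NIP	CaNIP1-8	Ca_00436	Ca1	3579756	3581062	5.73	25.65	0.822	plas
NIP	CaNIP1-9	Ca_00437	Ca1	3583849	3585825	6.31	29.8	0.501	plas
NIP	CaNIP2-1	Ca_21333	Ca3	3854949	3859331	8.81	28.65	0.354	plas
NIP	CaNIP3-1	Ca_02921	Ca1	8870515	8872730	9.09	31.93	0.361	plas
NIP	CaNIP3-2	Ca_22848	Ca5	17858736	17862203	6.47	26.55	0.713	plas
NIP	CaNIP3-3	Ca_25553	scaffold590	19540	20529	5.44	21.78	0.773	plas
NIP	CaNIP3-4	Ca_04355	Ca4	11227522	11231177	8.56	30.7	0.502	plas
NIP	CaNIP4-1	Ca_07775	Ca4	1463846	1467215	8.72	36.17	0.504	plas
NIP	CaNIP6-1	Ca_22925	Ca6	53303745	53307875	8.49	25.56	0.228	vacu
SIP	CaSIP1-2	Ca_19143	Ca2	6911037	6913006	6.3	22.93	0.979	vacu
SIP	CaSIP1-1	Ca_08262	Ca3	26454060	26457001	8.89	26.44	0.697	vacu
SIP	CaSIP2-1	Ca_08136	Ca3	27710934	27713756	9.43	26.11	0.603	vacu
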