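# Bundled drug-like molecule library: id<TAB>SMILES, one per line.
mol001	c1ccncc1
mol002	Cc1ccncc1
mol003	CCc1ccncc1
mol004	c1ccc(N)cc1
mol005	Cc1ccc(N)cc1
mol006	Nc1ccccc1O
mol007	Nc1ccc(Cl)cc1
mol008	Nc1ccc(F)cc1
mol009	Nc1ccc(Br)cc1
mol010	Nc1ccc(C)cc1C
mol011	c1ccc2ncccc2c1
mol012	c1ccc2[nH]ccc2c1
mol013	Cc1cc2ccccc2[nH]1
mol014	c1cnc2ccccc2n1
mol015	c1cnccn1
mol016	Cc1cnccn1
mol017	c1cncnc1
mol018	Nc1ncnc2[nH]cnc12
mol019	Cn1cnc2c1c(=O)n(C)c(=O)n2C
mol020	Cn1cnc2c1c(=O)[nH]c(=O)n2C
mol021	CN1CCCC1c1cccnc1
mol022	OCc1ccncc1
mol023	NCc1ccccc1
mol024	CNCc1ccccc1
mol025	CN(C)Cc1ccccc1
mol026	NCCc1ccccc1
mol027	NC(C)c1ccccc1
mol028	CC(N)Cc1ccccc1
mol029	CNC(C)Cc1ccccc1
mol030	CC(CN(C)C)c1ccccc1
mol031	c1ccc(-c2ccncc2)cc1
mol032	c1ccc(CNc2ccccc2)cc1
mol033	CN(c1ccccc1)c1ccccc1
mol034	O=C(N)c1ccccc1
mol035	O=C(N)c1ccncc1
mol036	O=C(NC)c1ccccc1
mol037	O=C(Nc1ccccc1)C
mol038	CC(=O)Nc1ccc(O)cc1
mol039	CC(=O)Nc1ccccc1O
mol040	O=C(O)c1ccccc1N
mol041	O=C(O)c1ccc(N)cc1
mol042	Nc1ccc(S(N)(=O)=O)cc1
mol043	NS(=O)(=O)c1ccccc1
mol044	CC(=O)Nc1ccc(S(N)(=O)=O)cc1
mol045	O=[N+]([O-])c1ccccc1
mol046	O=[N+]([O-])c1ccc(O)cc1
mol047	O=[N+]([O-])c1ccc(C)cc1
mol048	c1cc[nH]c1
mol049	Cc1ccc[nH]1
mol050	c1cnc[nH]1
mol051	Cc1cnc[nH]1
mol052	c1cocn1
mol053	c1cscn1
mol054	Cc1nccs1
mol055	Cc1occc1C(=O)N
mol056	c1ccc(-n2cccn2)cc1
mol057	Cn1ccnc1
mol058	Cc1ncc([N+](=O)[O-])n1C
mol059	NCc1ccco1
mol060	NCc1cccs1
mol061	Nc1nc2ccccc2s1
mol062	Nc1nc2ccccc2o1
mol063	Nc1ccccn1
mol064	Nc1cccnc1
mol065	Nc1ncccn1
mol066	Nc1nccs1
mol067	CCOC(=O)c1ccccc1N
mol068	COc1ccc(CCN)cc1
mol069	COc1ccc(CC(N)C)cc1
mol070	COc1cc2c(cc1OC)CCN(C)C2
mol071	NCCc1c[nH]c2ccccc12
mol072	NC(Cc1c[nH]c2ccccc12)C(=O)O
mol073	NC(Cc1ccccc1)C(=O)O
mol074	NC(Cc1ccc(O)cc1)C(=O)O
mol075	NC(Cc1c[nH]cn1)C(=O)O
mol076	OC(c1ccccc1)C1NCCCC1
mol077	OC(CNC)c1ccccc1
mol078	CNCC(O)c1ccc(O)c(O)c1
mol079	NCC(O)c1ccc(O)c(O)c1
mol080	CC(C)NCC(O)c1ccc(O)c(O)c1
mol081	CC(C)NCC(O)COc1ccccc1
mol082	CC(C)NCC(O)COc1cccc2ccccc12
mol083	CCN(CC)CCNC(=O)c1ccc(N)cc1
mol084	CN1CCN(c2ccccc2)CC1
mol085	CN1CCN(c2ccc(Cl)cc2)CC1
mol086	c1ccc(N2CCNCC2)cc1
mol087	O=C(c1ccccc1)N1CCNCC1
mol088	c1ccc(CN2CCCCC2)cc1
mol089	c1ccc(CN2CCOCC2)cc1
mol090	O=C1CCCN1c1ccccc1
mol091	CC(=O)N1CCN(c2ccccc2)CC1
mol092	CN(C)c1ccccc1
mol093	CN(C)c1ccc(C=O)cc1
mol094	CN(C)c1ccc(N=Nc2ccccc2)cc1
mol095	Clc1ccccc1Nc1ccccc1
mol096	O=C(O)c1ccccc1Nc1ccccc1
mol097	O=C(O)c1ccccc1Nc1ccccc1Cl
mol098	Cc1ccccc1Nc1ncccn1
mol099	Nc1nc(N)nc(-c2ccccc2)n1
mol100	c1ccccc1
mol101	Cc1ccccc1
mol102	CCc1ccccc1
mol103	CC(C)c1ccccc1
mol104	CCCc1ccccc1
mol105	Cc1ccccc1C
mol106	Cc1ccc(C)cc1
mol107	Cc1cccc(C)c1
mol108	Oc1ccccc1
mol109	Oc1ccc(C)cc1
mol110	Oc1ccc(O)cc1
mol111	Oc1ccccc1O
mol112	COc1ccccc1
mol113	COc1ccc(C)cc1
mol114	COc1ccc(OC)cc1
mol115	COc1ccccc1OC
mol116	Clc1ccccc1
mol117	Clc1ccc(Cl)cc1
mol118	Fc1ccccc1
mol119	Fc1ccc(F)cc1
mol120	Brc1ccccc1
mol121	Ic1ccccc1
mol122	FC(F)(F)c1ccccc1
mol123	O=Cc1ccccc1
mol124	O=Cc1ccc(O)cc1
mol125	O=Cc1ccc(OC)cc1
mol126	CC(=O)c1ccccc1
mol127	CC(=O)c1ccc(C)cc1
mol128	CC(=O)c1ccc(O)cc1
mol129	O=C(O)c1ccccc1
mol130	O=C(O)c1ccc(C)cc1
mol131	O=C(O)c1ccc(O)cc1
mol132	O=C(O)c1ccc(Cl)cc1
mol133	CC(=O)Oc1ccccc1C(=O)O
mol134	COC(=O)c1ccccc1
mol135	CCOC(=O)c1ccccc1
mol136	COC(=O)c1ccc(O)cc1
mol137	CC(C)Cc1ccc(C(C)C(=O)O)cc1
mol138	OCc1ccccc1
mol139	OCCc1ccccc1
mol140	OC(C)c1ccccc1
mol141	c1ccc(-c2ccccc2)cc1
mol142	c1ccc(Cc2ccccc2)cc1
mol143	c1ccc(Oc2ccccc2)cc1
mol144	c1ccc(COc2ccccc2)cc1
mol145	c1ccc2ccccc2c1
mol146	Cc1ccc2ccccc2c1
mol147	Oc1ccc2ccccc2c1
mol148	c1ccc2c(c1)ccc1ccccc12
mol149	c1ccoc1
mol150	Cc1ccco1
mol151	O=Cc1ccco1
mol152	c1ccsc1
mol153	Cc1cccs1
mol154	O=Cc1cccs1
mol155	Cc1cc(C)cc(C)c1
mol156	Oc1cc(C)ccc1C(C)C
mol157	CC(C)=CCc1ccccc1O
mol158	Oc1ccccc1-c1ccccc1
mol159	O=C(Oc1ccccc1)c1ccccc1
mol160	CSc1ccccc1
mol161	Sc1ccccc1
mol162	OS(=O)(=O)c1ccccc1
mol163	CCCCCc1ccccc1
mol164	NCC
mol165	CCCN
mol166	CCCCN
mol167	CC(C)N
mol168	CNC
mol169	CN(C)C
mol170	CCNCC
mol171	NCCO
mol172	NCCCO
mol173	NCCN
mol174	NCCCN
mol175	OCCNCCO
mol176	C1CCNCC1
mol177	CC1CCNCC1
mol178	CN1CCCCC1
mol179	C1CCNC1
mol180	CN1CCCC1
mol181	C1COCCN1
mol182	CN1CCOCC1
mol183	C1CNCCN1
mol184	CN1CCNCC1
mol185	O=C1CCCCN1
mol186	O=C1CCCN1
mol187	O=C1CCCN1C
mol188	NC(=O)C
mol189	NC(=O)CC
mol190	CNC(=O)C
mol191	CC(=O)NCC
mol192	NC(C)C(=O)O
mol193	NCC(=O)O
mol194	NC(CC(C)C)C(=O)O
mol195	NC(CO)C(=O)O
mol196	NC(CS)C(=O)O
mol197	NC(CCC(=O)O)C(=O)O
mol198	NC(CCCCN)C(=O)O
mol199	N#CC
mol200	N#CCC
mol201	CC(=O)NC1CCCCC1
mol202	NC1CCCCC1
mol203	CC
mol204	CCC
mol205	CCCC
mol206	CCCCC
mol207	CCCCCC
mol208	CC(C)C
mol209	CC(C)(C)C
mol210	C1CCCCC1
mol211	CC1CCCCC1
mol212	C1CCCC1
mol213	C1CCCCCC1
mol214	CO
mol215	CCO
mol216	CCCO
mol217	CC(C)O
mol218	CC(C)(C)O
mol219	OCCO
mol220	OCC(O)CO
mol221	CCOCC
mol222	C1CCOC1
mol223	C1CCOCC1
mol224	CC(=O)C
mol225	CCC(=O)C
mol226	O=C1CCCCC1
mol227	CC(=O)O
mol228	CCC(=O)O
mol229	CCCC(=O)O
mol230	OC(=O)CC(=O)O
mol231	OC(=O)CCC(=O)O
mol232	CC(O)C(=O)O
mol233	OC(=O)C=CC(=O)O
mol234	CC(=O)OCC
mol235	CSC
mol236	CCS
mol237	OC1CCCCC1
mol238	O=CC
mol239	O=CCC
mol240	C=CC=C
mol241	CC=CC
mol242	ClCCCl
mol243	ClC(Cl)Cl
mol244	FC(F)(F)CO
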