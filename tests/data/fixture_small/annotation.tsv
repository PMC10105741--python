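cell_id	sample_id	group	clinical_score	n_genes_detected	mito_fraction	uniquely_mapped_reads	n_splices
CASE1_c001	CASE1	intermediate	3	4152	0.0387152	1037060	207665
CASE1_c002	CASE1	intermediate	3	7868	0.02	914571	184255
CASE1_c003	CASE1	intermediate	3	5774	0.1	829155	166487
CASE1_c004	CASE1	intermediate	3	5311	0.0674155	1066113	208768
CASE1_c005	CASE1	intermediate	3	7745	0.05608	1110407	221145
CASE1_c006	CASE1	intermediate	3	5529	0.02	1046571	208127
CASE1_c007	CASE1	intermediate	3	6587	0.02	1067622	214262
CASE1_c008	CASE1	intermediate	3	6575	0.02	867001	171765
CASE1_c009	CASE1	intermediate	3	7571	0.0683959	988593	190114
CASE1_c010	CASE1	intermediate	3	6644	0.02	1017086	200691
CASE1_c011	CASE1	intermediate	3	4730	0.0969774	1071131	214798
CASE1_c012	CASE1	intermediate	3	5212	0.0445148	808012	161678
CASE1_c013	CASE1	intermediate	3	6886	0.02	844945	172349
CASE1_c014	CASE1	intermediate	3	5446	0.0510204	1009241	200881
CASE1_c015	CASE1	intermediate	3	7209	0.119499	1167196	233795
CASE2_c001	CASE2	TCA	5	4316	0.02	1043897	253687
CASE2_c002	CASE2	TCA	5	5447	0.02	1103962	276135
CASE2_c003	CASE2	TCA	5	7866	0.0539836	800126	199749
CASE2_c004	CASE2	TCA	5	7531	0.02	1015700	252772
CASE2_c005	CASE2	TCA	5	7073	0.133194	813709	203733
CASE2_c006	CASE2	TCA	5	5179	0.0734079	1032283	257084
CASE2_c007	CASE2	TCA	5	5187	0.17526	851458	210071
CASE2_c008	CASE2	TCA	5	6290	0.107405	1024907	256641
CASE2_c009	CASE2	TCA	5	6387	0.0744444	1146139	286889
CASE2_c010	CASE2	TCA	5	4682	0.0718987	810670	202966
CASE2_c011	CASE2	TCA	5	5194	0.02	898297	223458
CASE2_c012	CASE2	TCA	5	5793	0.0813172	914485	229561
CASE2_c013	CASE2	TCA	5	4463	0.02	1148307	282264
CASE2_c014	CASE2	TCA	5	6144	0.0804428	1151347	288304
CASE2_c015	CASE2	TCA	5	6651	0.02	821633	205517
CTRL1_c001	CTRL1	control	0	2000	0.0682703	1127115	172437
CTRL1_c002	CTRL1	control	0	9500	0.0514506	946188	142091
CTRL1_c003	CTRL1	control	0	7022	0.5	818120	122659
CTRL1_c004	CTRL1	control	0	2000	0.050303	981430	149777
CTRL1_c005	CTRL1	control	0	9500	0.0979221	803203	123144
CTRL1_c006	CTRL1	control	0	4554	0.0806641	919546	138266
CTRL1_c007	CTRL1	control	0	5124	0.02	1025286	154891
CTRL1_c008	CTRL1	control	0	5598	0.084623	865461	129982
CTRL1_c009	CTRL1	control	0	7499	0.02	836198	125638
CTRL1_c010	CTRL1	control	0	5415	0.0685549	944895	144046
CTRL1_c011	CTRL1	control	0	7287	0.0342928	1172771	179625
CTRL1_c012	CTRL1	control	0	5076	0.0958893	910944	139867
CTRL1_c013	CTRL1	control	0	5833	0.0543368	947796	143024
CTRL1_c014	CTRL1	control	0	6511	0.0594529	1022601	154853
CTRL1_c015	CTRL1	control	0	7057	0.0692308	806337	120957
CTRL2_c001	CTRL2	control	0	7575	0.110055	1133601	170334
CTRL2_c002	CTRL2	control	0	4490	0.0377596	937481	141234
CTRL2_c003	CTRL2	control	0	6688	0.0765714	1087047	163780
CTRL2_c004	CTRL2	control	0	5738	0.06751	1137065	171294
CTRL2_c005	CTRL2	control	0	5091	0.0748425	963302	145203
CTRL2_c006	CTRL2	control	0	7551	0.06947	1067101	160359
CTRL2_c007	CTRL2	control	0	5163	0.102927	1187414	184047
CTRL2_c008	CTRL2	control	0	7447	0.0610112	1043112	158534
CTRL2_c009	CTRL2	control	0	7988	0.114025	1171951	181434
CTRL2_c010	CTRL2	control	0	7253	0.02	903116	141127
CTRL2_c011	CTRL2	control	0	5845	0.0635953	885912	132980
CTRL2_c012	CTRL2	control	0	6629	0.0674951	1032196	155691
CTRL2_c013	CTRL2	control	0	4238	0.0477457	867679	129492
CTRL2_c014	CTRL2	control	0	6051	0.0652292	975807	147658
CTRL2_c015	CTRL2	control	0	6727	0.111106	927221	138279
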