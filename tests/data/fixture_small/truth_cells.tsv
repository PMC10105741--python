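cell_id	severity	qc_fail
CASE1_c001	0.50163	False
CASE1_c002	0.51761	False
CASE1_c003	0.501758	False
CASE1_c004	0.462582	False
CASE1_c005	0.496097	False
CASE1_c006	0.488516	False
CASE1_c007	0.508641	False
CASE1_c008	0.484336	False
CASE1_c009	0.422588	False
CASE1_c010	0.476476	False
CASE1_c011	0.497753	False
CASE1_c012	0.502166	False
CASE1_c013	0.528934	False
CASE1_c014	0.496425	False
CASE1_c015	0.509259	False
CASE2_c001	0.930381	False
CASE2_c002	1	False
CASE2_c003	0.999972	False
CASE2_c004	1	False
CASE2_c005	1	False
CASE2_c006	0.994904	False
CASE2_c007	0.973492	False
CASE2_c008	1	False
CASE2_c009	1	False
CASE2_c010	1	False
CASE2_c011	0.979216	False
CASE2_c012	1	False
CASE2_c013	0.954981	False
CASE2_c014	1	False
CASE2_c015	1	False
CTRL1_c001	0.0241527	True
CTRL1_c002	0	True
CTRL1_c003	0	True
CTRL1_c004	0.0280134	True
CTRL1_c005	0.038809	True
CTRL1_c006	0	False
CTRL1_c007	0.00946773	False
CTRL1_c008	0	False
CTRL1_c009	0	False
CTRL1_c010	0.0225597	False
CTRL1_c011	0.0289069	False
CTRL1_c012	0.0359807	False
CTRL1_c013	0.0083238	False
CTRL1_c014	0.0180774	False
CTRL1_c015	0	False
CTRL2_c001	0	False
CTRL2_c002	0	False
CTRL2_c003	0	False
CTRL2_c004	0	False
CTRL2_c005	0	False
CTRL2_c006	0	False
CTRL2_c007	0.0532492	False
CTRL2_c008	0.0212338	False
CTRL2_c009	0.0476917	False
CTRL2_c010	0.0597967	False
CTRL2_c011	0	False
CTRL2_c012	0.0102226	False
CTRL2_c013	0	False
CTRL2_c014	0.0103344	False
CTRL2_c015	0	False
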