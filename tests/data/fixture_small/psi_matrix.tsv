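event_id	CTRL1_c001	CTRL1_c002	CTRL1_c003	CTRL1_c004	CTRL1_c005	CTRL1_c006	CTRL1_c007	CTRL1_c008	CTRL1_c009	CTRL1_c010	CTRL1_c011	CTRL1_c012	CTRL1_c013	CTRL1_c014	CTRL1_c015	CTRL2_c001	CTRL2_c002	CTRL2_c003	CTRL2_c004	CTRL2_c005	CTRL2_c006	CTRL2_c007	CTRL2_c008	CTRL2_c009	CTRL2_c010	CTRL2_c011	CTRL2_c012	CTRL2_c013	CTRL2_c014	CTRL2_c015	CASE1_c001	CASE1_c002	CASE1_c003	CASE1_c004	CASE1_c005	CASE1_c006	CASE1_c007	CASE1_c008	CASE1_c009	CASE1_c010	CASE1_c011	CASE1_c012	CASE1_c013	CASE1_c014	CASE1_c015	CASE2_c001	CASE2_c002	CASE2_c003	CASE2_c004	CASE2_c005	CASE2_c006	CASE2_c007	CASE2_c008	CASE2_c009	CASE2_c010	CASE2_c011	CASE2_c012	CASE2_c013	CASE2_c014	CASE2_c015
EV_DRIVER	0.301308	0.18443	0.196342	0.283707	0.390176	0.358484	0.291164	0.257238	0.291874	0.361829	0.401513	0.273485	0.272551	0.22506	0.259923	0.296458	0.306106	0.259664	0.257633	0.341407	0.316261	0.442908	0.384946	0.194951	0.288667	0.319845	0.413584	0.230455	0.199168	0.327947	0.508392	0.616455	0.573561	0.402781	0.513049	0.50282	0.526607	0.449154	0.468024	0.512007	0.548213	0.459371	0.498526	0.533615	0.462809	0.649672	0.690561	0.744815	0.642302	0.708586	0.777184	0.755641	0.63517	0.769618	0.746818	0.598833	0.608197	0.586187	0.801878	0.651487
EV_MXE	0.698692	0.81557	0.803658	0.716293	0.609824	0.641516	0.708836	0.742762	0.708126	0.638171	0.598487	0.726515	0.727449	0.77494	0.740077	0.703542	0.693894	0.740336	0.742367	0.658593	0.683739	0.557092	0.615054	0.805049	0.711333	0.680155	0.586416	0.769545	0.800832	0.672053	0.491608	0.383545	0.426439	0.597219	0.486951	0.49718	0.473393	0.550846	0.531976	0.487993	0.451787	0.540629	0.501474	0.466385	0.537191	0.350328	0.309439	0.255185	0.357698	0.291414	0.222816	0.244359	0.36483	0.230382	0.253182	0.401167	0.391803	0.413813	0.198122	0.348513
EV_ENH01	0.329233	0.281872	0.19805	0.326411	0.390159	0.375721	0.218651	0.27287	0.232393	0.335422	0.441645	0.335406	0.467703	0.319152	0.292308	0.338912	0.423816	0.286946	0.277003	0.309436	0.494979	0.543308	0.350363	0.228289	0.293921	0.40204	0.402576	0.283216	0.218022	0.256731	0.530009	0.659338	0.42794	0.302764	0.517153	0.565919	0.461018	0.339697	0.398021	0.540212	0.575348	0.488515	0.715209	0.511404	0.433581	0.515533	0.649993	0.533852	0.543408	0.610126	0.737187	NA	0.485253	0.598061	0.789368	0.54981	NA	0.525995	0.728415	0.508336
EV_REP01	0.577954	0.722434	0.73243	0.564184	0.636852	0.584599	0.668944	0.70335	0.691849	0.618084	0.665863	0.716181	0.708646	0.699681	0.687414	0.726308	0.715397	0.682549	0.604856	0.635343	0.664071	0.474873	0.617775	0.754972	0.685537	0.570835	0.704617	0.62184	0.656296	0.667213	0.383938	0.336382	0.415077	0.515881	0.63411	0.477295	0.498943	0.592583	0.50495	0.527135	0.607838	0.479762	0.516248	0.517419	0.588108	0.317304	0.397557	0.330556	0.287032	0.392027	0.273641	0.315134	0.420237	NA	NA	0.402338	0.411705	0.371297	0.222944	0.433529
EV_N0001	0.708985	0.727527	0.825966	0.814546	0.842192	0.760364	0.786482	0.79512	NA	0.848374	0.829878	0.713602	0.70177	0.833016	0.821045	0.702674	0.743035	0.842019	0.713393	0.715725	0.737972	0.837248	0.712178	0.6617	0.73056	0.798715	0.687483	0.756501	0.766993	0.747109	0.760461	0.771937	0.661452	0.849011	0.882982	0.673093	0.72666	0.777942	0.693074	0.759886	0.865386	0.808029	0.863739	0.665756	0.830729	0.763265	0.775073	0.764371	0.769482	0.802862	0.786833	0.78519	0.710742	0.723155	0.740624	0.879192	0.771072	0.722393	0.830281	0.758678
EV_N0002	0.496351	0.675084	0.591762	0.422154	0.611915	0.616352	0.495002	0.52443	0.625486	0.705034	0.6438	0.564187	0.644694	0.600208	0.657004	0.575295	0.622248	0.543052	0.630681	0.585264	0.634173	0.493029	0.583537	0.578613	0.67501	0.598146	0.596307	0.618317	0.624771	0.540453	0.640433	0.573876	0.549346	0.661618	0.545863	0.522263	0.602579	0.626489	0.5072	0.614021	0.568222	0.707794	0.545894	0.593462	0.629106	0.590882	0.604591	0.449897	0.656383	0.638039	0.642152	0.615553	0.436085	0.585804	0.578252	0.539205	0.56512	0.612169	0.6466	0.605089
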