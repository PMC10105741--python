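gene_id	module	switch_center	switch_direction	hub_target_class	is_hub
G0001	1	NA	NA	none	False
G0002	1	NA	NA	none	False
G0003	2	NA	NA	none	False
G0004	2	NA	NA	none	False
G0005	3	NA	NA	none	False
G0006	3	NA	NA	none	False
G0007	4	NA	NA	none	False
G0008	4	NA	NA	none	False
G0009	0	0.432217	up	none	False
G0010	0	0.505668	down	none	False
G0011	0	NA	NA	activated	False
G0012	0	NA	NA	activated	False
G0013	0	NA	NA	repressed	False
G0014	0	NA	NA	repressed	False
G0015	0	NA	NA	none	False
G0016	0	NA	NA	none	False
G0017	0	NA	NA	none	False
G0018	0	NA	NA	none	False
HUB	0	NA	NA	none	True
MT-1	0	NA	NA	none	False
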