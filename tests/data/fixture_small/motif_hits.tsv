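gene_id	n_sites
G0001	5
G0002	1
G0003	1
G0004	2
G0005	0
G0006	5
G0007	2
G0008	4
G0009	2
G0010	0
G0011	0
G0012	0
G0013	3
G0014	2
G0015	0
G0016	0
G0017	0
G0018	0
HUB	0
MT-1	0
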