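COMPLEX_EXAMPLE	na	G0009	HUB	MT-1
SET_MODULE1	na	G0001	G0002
SET_MODULE2	na	G0003	G0004
SET_MODULE3	na	G0005	G0006
SET_MODULE4	na	G0007	G0008
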