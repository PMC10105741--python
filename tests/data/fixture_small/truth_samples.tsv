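sample_id	severity
CASE1	0.5
CASE2	1
CTRL1	0
CTRL2	0
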