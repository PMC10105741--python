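G0011
G0012
G0013
G0014
G0017
G0018
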