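MT-1
HUB
G0001
G0002
G0003
G0004
G0005
G0006
G0007
G0008
G0009
G0010
G0011
G0012
G0013
G0014
G0015
G0016
G0017
G0018
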