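EV_ENH01
EV_MXE
EV_N0001
EV_REP01
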