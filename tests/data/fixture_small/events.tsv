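event_id	gene_id	type	inclusion_isoforms	total_isoforms
EV_DRIVER	GDRIVER	SE	EV_DRIVER_inc	EV_DRIVER_exc,EV_DRIVER_inc
EV_ENH01	GT001	SE	EV_ENH01_inc	EV_ENH01_exc,EV_ENH01_inc
EV_MXE	GDRIVER	MX	EV_MXE_inc	EV_MXE_exc,EV_MXE_inc
EV_N0001	GN0001	SE	EV_N0001_inc	EV_N0001_exc,EV_N0001_inc
EV_N0002	GN0002	A5	EV_N0002_inc	EV_N0002_exc,EV_N0002_inc
EV_REP01	GR001	SE	EV_REP01_inc	EV_REP01_exc,EV_REP01_inc
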