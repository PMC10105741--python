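event_id	driver_target_class	is_driver	mxe_partner
EV_DRIVER	none	True	EV_MXE
EV_ENH01	enhanced	False	NA
EV_MXE	none	False	EV_DRIVER
EV_N0001	none	False	NA
EV_N0002	none	False	NA
EV_REP01	repressed	False	NA
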