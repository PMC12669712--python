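entity_a	entity_b	effect
KSR1	STK4	up-regulates activity
STK4	LATS1	up-regulates activity
LATS1	YAP1	down-regulates activity
KSR1	RAF1	up-regulates activity
RAF1	MAP2K1	up-regulates activity
MAP2K1	MAPK1	up-regulates activity
MAPK1	YAP1	down-regulates activity
KSR1	YAP1	unknown
RHOA	LATS1	up-regulates activity
STK4	RHOA	unknown
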