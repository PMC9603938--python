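taxon	arm_id	fragments
annulus-group standard	IS	abcdefghijklmnopqr
annulus-group standard	IL	abcdefghijklmnopqr
annulus-group standard	IIS	abcdefghijklmnopqr
annulus-group standard	IIL	abcdefghijklmnopqr
annulus-group standard	IIIS	abcdefghijklmnopqr
annulus-group standard	IIIL	abcdefghijklmnopqr
S. ustulatum	IL	abcdefghijklmnopqr
S. ustulatum	IIL	aedhionjkbcfglmqpr
S. ustulatum	IIIS	abcdefghijklmnopqr
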