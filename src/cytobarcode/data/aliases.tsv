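alias	canonical	note
IIL-3	IIL eu, us-1	fixed-series name for the same inversion
IIL eu-1	IIL eu, us-1	polymorphism name in S. annulus
IIIL eu-5	IIIL-1	polymorphism name in S. annulus
IS-1	IS-2	running text vs table naming discrepancy; table spelling canonical, unresolved in the source data
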