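name	ss	si	ii
IL us-1	5	6	8
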