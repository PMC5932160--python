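sample	group	replicate
mock_r1	mock	1
mock_r2	mock	2
mock_r3	mock	3
mock_r4	mock	4
treat_r1	treatment	1
treat_r2	treatment	2
treat_r3	treatment	3
treat_r4	treatment	4
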