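sample_id	location	year	length_mm
s0	X	2013	22.0
s1	X	2013	24.0
s2	X	2013	26.0
s3	X	2013	28.0
s4	X	2013	30.0
s5	Y	2013	32.0
s6	Y	2013	34.0
s7	Y	2013	36.0
s8	Y	2013	38.0
s9	Y	2013	40.0
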