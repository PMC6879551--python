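sample_id	L1|h0	L1|h1	L2|h0	L2|h1	L3|h0	L3|h1	L4|h0	L4|h1	L5|h0	L5|h1	L6|h0	L6|h1
s0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	0.0	1.0	0.0	1.0	0.0
s1	1.0	1.0	1.0	1.0	1.0	1.0	1.0	0.0	1.0	0.0	1.0	0.0
s2	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	0.0
s3	1.0	0.0	NA	NA	1.0	1.0	1.0	1.0	1.0	0.0	1.0	0.0
s4	1.0	0.0	NA	NA	1.0	0.0	1.0	0.0	1.0	1.0	1.0	0.0
s5	1.0	0.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	0.0	1.0	1.0
s6	1.0	0.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	0.0	1.0	1.0
s7	1.0	0.0	1.0	1.0	NA	NA	NA	NA	NA	NA	1.0	1.0
s8	1.0	0.0	NA	NA	NA	NA	NA	NA	1.0	0.0	1.0	0.0
s9	1.0	1.0	NA	NA	NA	NA	1.0	1.0	1.0	0.0	1.0	1.0
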