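node	dc	bc
GRIN2B	1	1
APP	2	0
FYN	1	0
NOS2	1	0
NOS3	0	0
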