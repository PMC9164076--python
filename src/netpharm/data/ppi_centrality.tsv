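node	dc	bc
GRIN2B	4	1
NOS2	4	0
APP	3	0
NOS3	2	0.43
FYN	2	0.04
OPRM1	1	0.39
PPARA	1	0.13
OPRD1	1	0
RPS6KA2	1	0
PPARG	0	0
RPS6KA3	0	0
NR1I2	0	0
SIGMAR1	0	0
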