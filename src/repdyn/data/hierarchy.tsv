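area	level
V1	1
V2	2
V3	3
V3A	4
V4	5
MT	6
V6	6
LO1	7
TEO	8
IPS1	9
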