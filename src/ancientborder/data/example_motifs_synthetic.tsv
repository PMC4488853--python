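haplogroup	variants
U	4:A
U5	4:A,17:T
U5b	4:A,17:T,42:C
H	9:G
J	55:T,88:A
T	101:C,140:G
K	4:A,203:T
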