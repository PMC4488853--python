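haplogroup	delta_age
U	20000
V	2500
H	-3000
J	-8000
T	-6000
K	-4500
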