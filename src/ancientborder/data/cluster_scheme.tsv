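token	cluster
U	HUNT
V	HUNT
H	FARM
J	FARM
T	FARM
K	FARM
HV	OTHER
D	OTHER
I	OTHER
N	OTHER
R	OTHER
W	OTHER
X	OTHER
Z	OTHER
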