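residue	ca	pre_pro
A	52.5	-2.0
C	58.2	-2.0
D	54.2	-2.0
E	56.6	-2.0
F	57.7	-2.0
G	45.1	-2.0
H	55.0	-2.0
I	61.1	-2.0
K	56.2	-2.0
L	55.1	-2.0
M	55.4	-2.0
N	53.1	-2.0
P	63.3	-2.0
Q	55.7	-2.0
R	56.0	-2.0
S	58.3	-2.0
T	61.8	-2.0
V	62.2	-2.0
W	57.5	-2.0
Y	57.9	-2.0
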