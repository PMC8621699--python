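#source: Bull & Breese (1974) Arch Biochem Biophys 161:665, surface tension / hydrophobicity (cal/mol)
A	610
R	690
N	890
D	610
C	360
Q	970
E	510
G	810
H	690
I	-1450
L	-1650
K	460
M	-660
F	-1520
P	-170
S	420
T	290
W	-1200
Y	-1430
V	-750
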