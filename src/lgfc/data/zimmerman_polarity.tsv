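#source: Zimmerman, Eliezer & Simha (1968) J Theor Biol 21:170, polarity scale
A	0.00
R	52.00
N	3.38
D	49.70
C	1.48
Q	3.53
E	49.90
G	0.00
H	51.60
I	0.13
L	0.13
K	49.50
M	1.43
F	0.35
P	1.58
S	1.67
T	1.66
W	2.10
Y	1.61
V	0.13
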