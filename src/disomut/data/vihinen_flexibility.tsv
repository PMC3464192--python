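# Vihinen normalized flexibility indices (Vihinen, Torkkila & Riikonen, 1994,
# Proteins 19:141-149). Higher values = more flexible. Sorting residues by this
# scale gives the conventional rigid-to-flexible axis ordering used for
# wild-type/mutant substitution heat maps.
residue	flexibility
W	0.904
C	0.906
F	0.915
I	0.927
Y	0.929
V	0.931
L	0.935
H	0.950
M	0.952
A	0.984
T	0.997
R	1.008
G	1.031
Q	1.037
S	1.046
N	1.048
P	1.049
D	1.068
E	1.094
K	1.102
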