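# Average masses (Da) of the free amino acids; peptide MW = sum - (n-1) * 18.01528
# source scale: standard average atomic weights
residue	mass
A	89.0932
R	174.2010
N	132.1179
D	133.1027
C	121.1582
E	147.1293
Q	146.1445
G	75.0666
H	155.1546
I	131.1729
L	131.1729
K	146.1876
M	149.2113
F	165.1891
P	115.1305
S	105.0926
T	119.1192
W	204.2252
Y	181.1885
V	117.1463
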