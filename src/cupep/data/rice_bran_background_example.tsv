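# Example background amino-acid composition (percent of residues) for
# rice bran protein, literature-informed midpoints; a config input, not a
# measured table. Synthetic example shipped with cupep.
residue	percent
A	6.0
C	1.5
D	5.0
E	12.0
F	4.5
G	6.5
H	2.0
I	3.5
K	4.5
L	7.0
M	2.0
N	4.0
P	9.0
Q	3.0
R	7.5
S	8.5
T	3.5
V	6.0
W	1.0
Y	3.0
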