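# Amino-acid residue partial molar volumes (cm^3/mol, 25 C), after
# Kharakoz DP, Biochemistry 1997, 36:10276-10285, as transcribed in the
# secondary literature. Used for the two 3-residue sub-window volume sums.
# residue	value
A	53.2
R	109.4
N	71.7
D	68.4
C	68.3
Q	88.1
E	84.7
G	37.3
H	91.1
I	101.8
L	101.8
K	101.3
M	97.7
F	118.2
P	75.6
S	54.9
T	71.2
W	141.4
Y	123.7
V	85.3
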