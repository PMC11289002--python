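amino_acid	frequency
A	0.082591
C	0.013815
D	0.054660
E	0.067274
F	0.038643
G	0.070778
H	0.022725
I	0.059165
K	0.058064
L	0.096605
M	0.024127
N	0.040645
P	0.047352
Q	0.039343
R	0.055361
S	0.066373
T	0.053559
V	0.068676
W	0.011012
Y	0.029232
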