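# Synthetic conventional-FFAT penalty matrix, derived from
# phospho_ffat_synthetic.tsv by the C4 transform (S,T -> 4; D,E -> 0).
# name: conventional_ffat_synthetic
# motif_class: conventional
residue	U1	U2	U3	U4	U5	U6	C1	C2	C3	C4	C5	C6	C7	D1	D2	D3	D4	D5	D6
A	1	1	1	1	1	1	2.5	5	5	3	0	0	2.5	1	1	1	1	1	1
C	1.5	1.5	1.5	1.5	1.5	1.5	3.5	5	5	4	1	0	3.5	1.5	1.5	1.5	1.5	1.5	1.5
D	0	0	0	0	0	0	0.5	5	5	0	2.5	0	0.5	0	0	0	0	0	0
E	0	0	0	0	0	0	0	5	5	0	2.5	0	0	0	0	0	0	0	0
F	2	2	2	2	2	2	3.5	0	0	4	2.5	0	3.5	2	2	2	2	2	2
G	1	1	1	1	1	1	2.5	5	5	3	1	0	2.5	1	1	1	1	1	1
H	2	2	2	2	2	2	3.5	5	5	4	2.5	0	3.5	2	2	2	2	2	2
I	2	2	2	2	2	2	3.5	3.5	3.5	4	2.5	0	3.5	2	2	2	2	2	2
K	2.5	2.5	2.5	2.5	2.5	2.5	4	5	5	4.5	3	0	4	2.5	2.5	2.5	2.5	2.5	2.5
L	2	2	2	2	2	2	3.5	3	3	4	2.5	0	3.5	2	2	2	2	2	2
M	2	2	2	2	2	2	3.5	3	3	4	2.5	0	3.5	2	2	2	2	2	2
N	1.5	1.5	1.5	1.5	1.5	1.5	2	5	5	2.5	2.5	0	2	1.5	1.5	1.5	1.5	1.5	1.5
P	1.5	1.5	1.5	1.5	1.5	1.5	3.5	5	5	4	3	0	3.5	1.5	1.5	1.5	1.5	1.5	1.5
Q	1.5	1.5	1.5	1.5	1.5	1.5	2	5	5	2.5	2.5	0	2	1.5	1.5	1.5	1.5	1.5	1.5
R	2.5	2.5	2.5	2.5	2.5	2.5	4	5	5	4.5	3	0	4	2.5	2.5	2.5	2.5	2.5	2.5
S	0.5	0.5	0.5	0.5	0.5	0.5	1	5	5	4	1	0	1	0.5	0.5	0.5	0.5	0.5	0.5
T	0.5	0.5	0.5	0.5	0.5	0.5	1	5	5	4	1.5	0	1	0.5	0.5	0.5	0.5	0.5	0.5
V	2	2	2	2	2	2	3.5	3.5	3.5	4	2	0	3.5	2	2	2	2	2	2
W	2	2	2	2	2	2	3.5	2	1.5	4	2.5	0	3.5	2	2	2	2	2	2
Y	2	2	2	2	2	2	3.5	1	0	4	2.5	0	3.5	2	2	2	2	2	2
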