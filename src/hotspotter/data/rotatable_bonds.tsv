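res	n_rotatable	n_sidechain_atoms
ALA	0	1
ARG	5	7
ASN	2	4
ASP	2	4
CYS	1	2
GLN	3	5
GLU	3	5
GLY	0	0
HIS	2	6
ILE	2	4
LEU	2	4
LYS	4	5
MET	3	4
PHE	2	7
PRO	0	3
SER	1	2
THR	1	3
TRP	2	10
TYR	2	8
VAL	1	3
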