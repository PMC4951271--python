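res	total	backbone	sidechain	polar	nonpolar
ALA	129.0	46.0	83.0	51.6	77.4
ARG	274.0	46.0	228.0	149.5	124.5
ASN	195.0	46.0	149.0	97.5	97.5
ASP	193.0	46.0	147.0	96.5	96.5
CYS	167.0	46.0	121.0	55.7	111.3
GLN	225.0	46.0	179.0	100.0	125.0
GLU	223.0	46.0	177.0	99.1	123.9
GLY	104.0	46.0	1.0	52.0	52.0
HIS	224.0	46.0	178.0	89.6	134.4
ILE	197.0	46.0	151.0	49.2	147.8
LEU	201.0	46.0	155.0	50.2	150.8
LYS	236.0	46.0	190.0	78.7	157.3
MET	224.0	46.0	178.0	56.0	168.0
PHE	240.0	46.0	194.0	43.6	196.4
PRO	159.0	46.0	113.0	45.4	113.6
SER	155.0	46.0	109.0	77.5	77.5
THR	172.0	46.0	126.0	73.7	98.3
TRP	285.0	46.0	239.0	61.1	223.9
TYR	263.0	46.0	217.0	65.8	197.2
VAL	174.0	46.0	128.0	49.7	124.3
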