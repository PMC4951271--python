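res	hydrophobicity	hydrophilicity	isoelectric_point	mass	contacts_14A	eiip	charge	volume	polarity	flexibility	helix_propensity	sheet_propensity	turn_propensity	polarizability	buriedness	steric_parameter
ALA	0.3100	-0.5000	6.0000	71.0800	16.2500	0.0373	0.0000	88.6000	8.1000	0.3570	1.4200	0.8300	0.6600	0.0460	0.3000	0.5200
ARG	-1.0100	3.0000	10.7600	156.1900	15.2000	0.0959	1.0000	173.4000	10.5000	0.5290	0.9800	0.9300	0.9500	0.2910	-1.4000	0.6800
ASN	-0.6000	0.2000	5.4100	114.1000	14.7000	0.0036	0.0000	114.1000	11.6000	0.4630	0.6700	0.8900	1.5600	0.1340	-0.5000	0.7600
ASP	-0.7700	3.0000	2.7700	115.0900	14.4500	0.1263	-1.0000	111.1000	13.0000	0.5110	1.0100	0.5400	1.4600	0.1050	-0.6000	0.7600
CYS	1.5400	-1.0000	5.0700	103.1400	18.7700	0.0829	0.0000	108.5000	5.5000	0.3460	0.7000	1.1900	1.1900	0.1280	0.9000	0.6200
GLN	-0.2200	0.2000	5.6500	128.1300	14.7100	0.0761	0.0000	143.8000	10.5000	0.4930	1.1100	1.1000	0.9800	0.1800	-0.7000	0.6800
GLU	-0.6400	3.0000	3.2200	129.1200	13.5700	0.0058	-1.0000	138.4000	12.3000	0.4970	1.5100	0.3700	0.7400	0.1510	-0.7000	0.6800
GLY	0.0000	0.0000	5.9700	57.0500	15.9700	0.0050	0.0000	60.1000	9.0000	0.5440	0.5700	0.7500	1.5600	0.0000	0.3000	0.0000
HIS	0.1300	-0.5000	7.5900	137.1400	16.2600	0.0242	0.0000	153.2000	10.4000	0.3230	1.0000	0.8700	0.9500	0.2300	-0.1000	0.7000
ILE	1.8000	-1.8000	6.0200	113.1600	18.7300	0.0000	0.0000	166.7000	5.2000	0.4620	1.0800	1.6000	0.4700	0.1860	0.7000	1.0200
LEU	1.7000	-1.8000	5.9800	113.1600	18.2200	0.0000	0.0000	166.7000	4.9000	0.3650	1.2100	1.3000	0.5900	0.1860	0.5000	0.9800
LYS	-0.9900	3.0000	9.7400	128.1700	13.1000	0.0371	1.0000	168.6000	11.3000	0.4660	1.1600	0.7400	1.0100	0.2190	-1.8000	0.6800
MET	1.2300	-1.3000	5.7400	131.1900	18.4500	0.0823	0.0000	162.9000	5.7000	0.2950	1.4500	1.0500	0.6000	0.2210	0.4000	0.7800
PHE	1.7900	-2.5000	5.4800	147.1800	18.5900	0.0946	0.0000	189.9000	5.2000	0.3140	1.1300	1.3800	0.6000	0.2900	0.5000	0.7000
PRO	0.7200	0.0000	6.3000	97.1200	14.2200	0.0198	0.0000	112.7000	8.0000	0.5090	0.5700	0.5500	1.5200	0.1310	-0.3000	0.3600
SER	-0.0400	0.3000	5.6800	87.0800	15.1800	0.0829	0.0000	89.0000	9.2000	0.5070	0.7700	0.7500	1.4300	0.0620	-0.1000	0.5300
THR	0.2600	-0.4000	5.6000	101.1000	15.7800	0.0941	0.0000	116.1000	8.6000	0.4440	0.8300	1.1900	0.9600	0.1080	-0.2000	0.9600
TRP	2.2500	-3.4000	5.8900	186.2100	18.0300	0.0548	0.0000	227.8000	5.4000	0.3050	1.0800	1.3700	0.9600	0.4090	0.3000	0.7000
TYR	0.9600	-2.3000	5.6600	163.1800	17.1700	0.0516	0.0000	193.6000	6.2000	0.4200	0.6900	1.4700	1.1400	0.2980	-0.4000	0.7000
VAL	1.2200	-1.5000	5.9600	99.1300	18.4300	0.0057	0.0000	140.0000	5.9000	0.3860	1.0600	1.7000	0.5000	0.1400	0.6000	1.0200
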