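res	ALA	ARG	ASN	ASP	CYS	GLN	GLU	GLY	HIS	ILE	LEU	LYS	MET	PHE	PRO	SER	THR	TRP	TYR	VAL
ALA	0.014	-0.047	-0.028	-0.036	0.072	-0.010	-0.030	0.000	0.006	0.084	0.079	-0.046	0.057	0.083	0.033	-0.002	0.012	0.105	0.045	0.057
ARG	-0.047	-0.247	0.091	0.517	-0.233	0.033	0.497	-0.000	-0.020	-0.273	-0.258	-0.250	-0.186	-0.271	-0.109	0.006	-0.039	-0.341	-0.145	-0.185
ASN	-0.028	0.091	0.054	0.069	-0.139	0.020	0.058	-0.000	-0.012	-0.162	-0.153	0.089	-0.111	-0.161	-0.065	0.004	-0.023	-0.202	-0.086	-0.110
ASP	-0.036	0.517	0.069	-0.311	-0.178	0.025	-0.326	-0.000	-0.015	-0.208	-0.196	0.514	-0.142	-0.207	-0.083	0.005	-0.030	-0.260	-0.111	-0.141
CYS	0.072	-0.233	-0.139	-0.178	0.356	-0.051	-0.148	0.000	0.030	0.416	0.393	-0.229	0.284	0.413	0.166	-0.009	0.060	0.520	0.222	0.282
GLN	-0.010	0.033	0.020	0.025	-0.051	0.007	0.021	-0.000	-0.004	-0.059	-0.056	0.033	-0.041	-0.059	-0.024	0.001	-0.009	-0.074	-0.032	-0.040
GLU	-0.030	0.497	0.058	-0.326	-0.148	0.021	-0.339	-0.000	-0.012	-0.173	-0.163	0.495	-0.118	-0.172	-0.069	0.004	-0.025	-0.216	-0.092	-0.117
GLY	0.000	-0.000	-0.000	-0.000	0.000	-0.000	-0.000	0.000	0.000	0.000	0.000	-0.000	0.000	0.000	0.000	-0.000	0.000	0.000	0.000	0.000
HIS	0.006	-0.020	-0.012	-0.015	0.030	-0.004	-0.012	0.000	0.003	0.035	0.033	-0.019	0.024	0.035	0.014	-0.001	0.005	0.044	0.019	0.024
ILE	0.084	-0.273	-0.162	-0.208	0.416	-0.059	-0.173	0.000	0.035	0.486	0.459	-0.267	0.332	0.483	0.194	-0.011	0.070	0.607	0.259	0.329
LEU	0.079	-0.258	-0.153	-0.196	0.393	-0.056	-0.163	0.000	0.033	0.459	0.433	-0.252	0.314	0.456	0.184	-0.010	0.066	0.574	0.245	0.311
LYS	-0.046	-0.250	0.089	0.514	-0.229	0.033	0.495	-0.000	-0.019	-0.267	-0.252	-0.253	-0.183	-0.266	-0.107	0.006	-0.039	-0.334	-0.143	-0.181
MET	0.057	-0.186	-0.111	-0.142	0.284	-0.041	-0.118	0.000	0.024	0.332	0.314	-0.183	0.227	0.330	0.133	-0.007	0.048	0.415	0.177	0.225
PHE	0.083	-0.271	-0.161	-0.207	0.413	-0.059	-0.172	0.000	0.035	0.483	0.456	-0.266	0.330	0.481	0.193	-0.011	0.070	0.604	0.258	0.328
PRO	0.033	-0.109	-0.065	-0.083	0.166	-0.024	-0.069	0.000	0.014	0.194	0.184	-0.107	0.133	0.193	0.078	-0.004	0.028	0.243	0.104	0.132
SER	-0.002	0.006	0.004	0.005	-0.009	0.001	0.004	-0.000	-0.001	-0.011	-0.010	0.006	-0.007	-0.011	-0.004	0.000	-0.002	-0.013	-0.006	-0.007
THR	0.012	-0.039	-0.023	-0.030	0.060	-0.009	-0.025	0.000	0.005	0.070	0.066	-0.039	0.048	0.070	0.028	-0.002	0.010	0.088	0.037	0.048
TRP	0.105	-0.341	-0.202	-0.260	0.520	-0.074	-0.216	0.000	0.044	0.607	0.574	-0.334	0.415	0.604	0.243	-0.013	0.088	0.759	0.324	0.412
TYR	0.045	-0.145	-0.086	-0.111	0.222	-0.032	-0.092	0.000	0.019	0.259	0.245	-0.143	0.177	0.258	0.104	-0.006	0.037	0.324	0.138	0.176
VAL	0.057	-0.185	-0.110	-0.141	0.282	-0.040	-0.117	0.000	0.024	0.329	0.311	-0.181	0.225	0.328	0.132	-0.007	0.048	0.412	0.176	0.223
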