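form	molecule	R	beta	Phi	phi1	phi2	phi3	phi4	phi5	Phi_suspect
dimer	A	5.150	127.9	-82.1	-82.1	-70.4	-168.4	71.9	-168.8	1
dimer	B	5.148	127.9	-88.8	-88.8	-70.3	-168.1	71.8	-168.9	1
tetramer	A	5.148	128.6	-82.3	-82.3	-70.4	-167.3	72.5	-167.4	1
tetramer	B	5.212	117.2	-80.1	-80.1	-76.3	176.8	64.2	-90.8	1
tetramer	C	5.110	122.0	158.6	158.6	-71.7	-50.5	60.1	-53.8	1
tetramer	D	4.313	150.6	-95.3	-95.3	-93.1	-100.2	70.6	-160.4	1
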