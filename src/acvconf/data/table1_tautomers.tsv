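name	level	R	beta	Phi	phi1	phi2	phi3	phi4	phi5	mu	dE	dG
N1	B3LYP/6-31G(d,p)	3.925	72.3	53.7	-74.1	144.7	-93.4	71.1	-73.3	5.375	0	0
N3	B3LYP/6-31G(d,p)	3.877	80.5	49.5	-48.4	155.0	-93.9	61.1	-88.0	11.183	25.529	24.811
N7	B3LYP/6-31G(d,p)	3.745	72.8	53.3	-79.9	136.9	-78.5	71.8	-91.5	7.785	17.516	17.689
OHC	B3LYP/6-31G(d,p)	3.839	72.9	53.4	-75.9	141.9	-87.0	71.1	-81.5	2.100	0.145	0.284
OHT	B3LYP/6-31G(d,p)	3.806	72.9	53.6	-76.2	140.7	-85.0	71.0	-84.9	2.105	0.719	0.830
N1	MP2/6-31G(d,p)	3.892	73.5	51.3	-71.9	150.3	-94.6	69.1	-75.4	6.207	0
N3	MP2/6-31G(d,p)	3.672	77.0	53.5	-45.9	149.1	-92.5	60.2	-92.6	12.220	25.457
N7	MP2/6-31G(d,p)	3.741	73.0	52.0	-76.4	140.5	-80.8	72.4	-92.7	9.841	19.302
OHC	MP2/6-31G(d,p)	3.826	73.5	51.7	-72.3	146.5	-89.2	70.4	-82.6	2.471	0.603
OHT	MP2/6-31G(d,p)	3.792	73.5	52.0	-72.4	145.0	-87.2	70.6	-86.1	3.437	1.131
N1	B3LYP/6-311++G(3df,pd)	3.963	72.5	54.3	-75.3	146.4	-88.5	69.8	-69.3	5.739	0
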