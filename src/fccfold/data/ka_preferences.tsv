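kappa	60	80	180	-130	-110	-10
30	0	0	0	0	0	0
40	0	0.05	0.01	0	0	0
50	0.21	0.73	0.18	0.06	0	0.05
60	1.24	1.5	0.34	0.49	0	0.38
70	17.87	1.76	0.14	0.55	0	0.95
80	11.08	0.59	0.21	0.51	0.02	1.65
90	1.28	0.58	0.31	0.64	0.25	2.44
100	0.87	0.68	0.39	0.98	0.56	2.98
110	0.72	0.70	0.47	1.29	0.96	2.14
120	0.28	0.56	0.57	1.22	1.78	1.04
130	0.08	0.24	0.47	1.39	2.08	0.57
140	0.04	0.10	0.40	1.99	2.03	0.43
150	0.02	0.02	0.21	7.43	17.46	0.60
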