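complex	dE	d	rho100	rho100_ancillary
2	-1.7	3.144	0.63	0.60
3	-1.4	3.060	0.60	0.64
4	-1.9	3.076	0.69	0.74
5	-0.9	3.124	0.50	0.56
6	-1.7	3.121	0.61	0.59
8	-2.8	3.136	0.66	0.56
9	-3.0	3.063	0.61	0.61
10	-2.5	3.033	0.76	0.74
11	-2.6	3.110	0.57	0.50
12	-3.5	3.051	0.71	0.46
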