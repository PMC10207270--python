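source	cluster_id	resid	rho100	dE	d
ATSP	c0-1	2JH-MK8	1.55	-3.4	2.710
ATSP	c0-2	TRP-ALA	0.77	-1.2	3.092
ATSP	c0-3	PHE-0EH	1.07	-2.1	2.927
ATSP	c1-1	2JH-MK8	1.38	-2.9	2.792
ATSP	c2-1	2JH-MK8	1.15	-2.3	2.875
ATSP	c2-2	PHE-0EH	1.62	-3.6	2.704
p53	c0-1	TRP-LYS	1.32	-2.8	2.800
p53	c1-1	PHE-SER	0.85	-1.5	2.997
p53	c1-2	PRO-GLU	0.92	-1.7	3.060
p53	c2-1	LYS-LEU	1.22	-2.5	2.829
p53	c2-2	LEU-PRO	1.24	-2.5	2.835
p53	c3-1	TRP-LYS	0.59	-0.7	3.357
p53	c3-2	LEU-ASN	0.51	-0.5	3.376
p53	c4-1	LYS-LEU	1.25	-2.6	2.821
pDIQ	c0-1	PHE-GLU	0.66	-0.9	3.126
pDIQ	c0-2	TRP-TRP	0.89	-1.6	2.943
pDIQ	c0-3	TRP-SER	1.34	-2.8	2.863
pDIQ	c1-1	PHE-GLU	0.97	-1.8	2.995
pDIQ	c1-2	TRP-SER	0.94	-1.7	2.993
pDIQ	c2-1	HIE-TRP	0.92	-1.7	2.989
pDIQ	c2-2	TRP-TRP	1.02	-1.9	2.943
4N5T-xray	ttb-1	-	1.01	-1.9	3.008
4N5T-xray	ttb-2	-	0.56	-0.6	3.273
4N5T-xray	ttb-3	-	1.08	-2.1	2.960
4N5T-xray	ttb-4	-	1.05	-2.0	2.997
4N5T-xray	ttb-5	-	1.02	-1.9	2.977
4N5T-xray	ttb-6	-	1.04	-2.0	2.971
4N5T-xray	ttb-7	-	1.16	-2.3	2.909
4N5T-xray	ttb-8	-	1.24	-2.5	2.841
4N5T-xray	ttb-9	-	1.29	-2.7	2.828
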