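metabolite	biochemical_name	obese_mean	obese_sd	lean_mean	lean_sd	p_value
PC aa C34:1	Phosphatidylcholine diacyl C34:1	213.02	124.93	313.65	188.48	0.042
PC aa C36:3	Phosphatidylcholine diacyl C36:3	136.34	55.02	181.21	73.58	0.017
PC aa C36:4	Phosphatidylcholine diacyl C36:4	169.75	47.87	202.41	68.46	0.049
PC aa C38:4	Phosphatidylcholine diacyl C38:4	135.81	66.55	181.75	86.61	0.045
PC aa C38:5	Phosphatidylcholine diacyl C38:5	66.1	42.79	98	54.63	0.016
PC aa C40:2	Phosphatidylcholine diacyl C40:2	0.48	0.16	0.59	0.2	0.014
PC aa C40:3	Phosphatidylcholine diacyl C40:3	0.78	0.45	1	0.47	0.033
PC aa C40:4	Phosphatidylcholine diacyl C40:4	3.31	1.71	4.52	2.28	0.028
PC aa C40:5	Phosphatidylcholine diacyl C40:5	14.83	13.34	23.34	16.81	0.05
PC aa C42:1	Phosphatidylcholine diacyl C42:1	0.15	0.04	0.17	0.04	0.005
PC aa C42:5	Phosphatidylcholine diacyl C42:5	0.34	0.12	0.4	0.1	0.02
PC aa C42:6	Phosphatidylcholine diacyl C42:6	0.83	0.23	1	0.3	0.02
PC ae C36:0	Phosphatidylcholine acyl-alkyl C36:0	0.92	0.55	1.18	0.59	0.048
PC ae C38:1	Phosphatidylcholine acyl-alkyl C38:1	2.35	1.87	3.62	2.49	0.05
PC ae C38:3	Phosphatidylcholine acyl-alkyl C38:3	3.51	2.18	4.86	2.7	0.049
PC ae C40:4	Phosphatidylcholine acyl-alkyl C40:4	3.19	1.36	4	1.57	0.036
PC ae C40:5	Phosphatidylcholine acyl-alkyl C40:5	2.2	1.33	2.94	1.52	0.036
PC ae C42:0	Phosphatidylcholine acyl-alkyl C42:0	1.03	0.3	1.29	0.45	0.017
PC ae C42:1	Phosphatidylcholine acyl-alkyl C42:1	0.72	0.18	0.92	0.35	0.008
PC ae C42:2	Phosphatidylcholine acyl-alkyl C42:2	0.83	0.53	1.17	0.7	0.046
PC ae C44:3	Phosphatidylcholine acyl-alkyl C44:3	0.13	0.03	0.16	0.04	0.006
PC ae C44:4	Phosphatidylcholine acyl-alkyl C44:4	0.16	0.07	0.18	0.05	0.015
lysoPC a C16:1	lysoPhosphatidylcholine acyl C16:1	10.5	3.68	12.69	3.92	0.049
lysoPC a C18:1	lysoPhosphatidylcholine acyl C18:1	90.23	58.24	121.75	62.9	0.048
Ser	Serine	108.43	47.37	81.63	31.65	0.009
Gly	Glycine	232.3	59.7	194.3	59.9	0.025
Arg	Arginine	152.8	38.5	132.2	39.2	0.031
C14	Tetradecanoylcarnitine	0.08	0.02	0.1	0.05	0.003
C14:1	Tetradecenoylcarnitine	0.12	0.03	0.14	0.03	0.003
C18:1	Octadecenoylcarnitine	0.15	0.05	0.21	0.09	0.002
SM (OH) C22:1	Hydroxysphingomyelin C22:1	4.19	2.75	3.16	1.56	0.04
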