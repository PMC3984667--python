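trait	unit	line	sex	diet	mean	sd
BW	g	BFMI	M	SMD	38.3	1.6
BW	g	BFMI	M	HFD	48.5	3.8
BW	g	BFMI	F	SMD	27.3	1.5
BW	g	BFMI	F	HFD	38.6	6.5
BW	g	B6	M	SMD	26.5	1.2
BW	g	B6	M	HFD	25.7	1.4
BW	g	B6	F	SMD	21.5	0.7
BW	g	B6	F	HFD	22.8	2.4
BW	g	F1	M	SMD	28.4	0.8
BW	g	F1	M	HFD	36.2	2.3
BW	g	F1	F	SMD	25	1
BW	g	F1	F	HFD	25.4	0.7
FAT	%	BFMI	M	SMD	23.89	3.49
FAT	%	BFMI	M	HFD	31.91	1.51
FAT	%	BFMI	F	SMD	20.79	4.15
FAT	%	BFMI	F	HFD	38.53	3.88
FAT	%	B6	M	SMD	5.87	2.119
FAT	%	B6	M	HFD	10.35	4.24
FAT	%	B6	F	SMD	6.87	2.37
FAT	%	B6	F	HFD	12.65	5.71
FAT	%	F1	M	SMD	5.14	2.25
FAT	%	F1	M	HFD	14.31	3.27
FAT	%	F1	F	SMD	9.42	1.22
FAT	%	F1	F	HFD	13.63	4.27
TG	mg/dl	BFMI	M	SMD	190.3	41.2
TG	mg/dl	BFMI	M	HFD	151.5	35.6
TG	mg/dl	BFMI	F	SMD	103.1	28
TG	mg/dl	BFMI	F	HFD	127.7	74
TG	mg/dl	B6	M	SMD	102.4	34.9
TG	mg/dl	B6	M	HFD	68.9	28.8
TG	mg/dl	B6	F	SMD	59.2	21
TG	mg/dl	B6	F	HFD	69.8	11.7
TG	mg/dl	F1	M	SMD	169.5	43.2
TG	mg/dl	F1	M	HFD	131.7	27.3
TG	mg/dl	F1	F	SMD	148.4	22
TG	mg/dl	F1	F	HFD	73.2	16.9
NEFA	mmol/l	BFMI	M	SMD	1	0.1
NEFA	mmol/l	BFMI	M	HFD	1	0.1
NEFA	mmol/l	BFMI	F	SMD	0.8	0.2
NEFA	mmol/l	BFMI	F	HFD	1	0.3
NEFA	mmol/l	B6	M	SMD	0.7	0.1
NEFA	mmol/l	B6	M	HFD	0.8	0.1
NEFA	mmol/l	B6	F	SMD	0.7	0.2
NEFA	mmol/l	B6	F	HFD	0.7	0.1
NEFA	mmol/l	F1	M	SMD	0.7	0.1
NEFA	mmol/l	F1	M	HFD	0.8	0.1
NEFA	mmol/l	F1	F	SMD	0.8	0.2
NEFA	mmol/l	F1	F	HFD	0.8	0.1
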