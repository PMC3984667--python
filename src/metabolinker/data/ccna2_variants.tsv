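variation_id	pos	ref	alt	known_id	region	function	effect
SNP1	36471433	G	A	rs49416676	promoter	TF-regulation	gain;silencing
SNP2	36471338	G	A	rs50741947	promoter	TF-regulation	gain;loss;enhancing
SNP3	36471316	A	G	rs46760941	promoter	TF-regulation	loss;silencing
SNP4	36471291	A	G	rs50888702	promoter	TF-regulation	loss;enhancing;silencing
SNP5	36471264	G	A	rs48075421	promoter	TF-regulation	gain;loss;enhancing;silencing
SNP6	36471206	A	G	rs45964814	promoter	TF-regulation	gain;enhancing
SNP7	36471126	C	G	rs51039343	promoter	TF-regulation	loss;enhancing;unchanged
DEL1	36471074	A	-		promoter	TF-regulation	gain;loss;silencing
SNP8	36471071	G	T		5'UTR	TF-regulation
SNP9	36470786	T	C		5'UTR	TF-regulation	gain;loss
SNP10	36470691	C	T		coding	synonymous coding	Leucin
SNP11	36467695	G	A	rs49497566	coding	synonymous coding	Glutamin
SNP12	36465032	T	C	rs29940755	3'UTR	unknown
SNP13	36464877	A	G	rs29939979	3'UTR	miRNA-regulation	gain
SNP14	36464857	G	A	rs29939976	3'UTR	miRNA-regulation	gain
SNP15	36464725	C	T	rs45880100	3'UTR	unknown
INS1	36464688	-	T	rs29939053	3'UTR	miRNA-regulation	gain
SNP16	36464653	G	C	rs29939050	3'UTR	unknown
SNP17	36464611	A	T	rs29939047	3'UTR	miRNA-regulation	gain
DEL2	36464525	ACAA	-		3'UTR	miRNA-regulation	loss
SNP18	36464511	A	G	rs29939044	3'UTR
SNP19	36464492	C	T	rs29938061	3'UTR	miRNA-regulation	gain
SNP20	36464477	A	G		3'UTR	miRNA-regulation	gain
INS2	36464469	-	G		3'UTR	miRNA-regulation	gain;loss
INS3	36464464	-	GTGTATATACATACACACACATATACAC		3'UTR	miRNA-regulation	enhancing;gain;loss
SNP21	36464447	G	C	rs47451785	3'UTR
SNP22	36464390	G	C	rs29938058	3'UTR	miRNA-regulation	loss
SNP23	36464274	C	T	rs29938055	3'UTR
SNP24	36463910	A	G	rs29944107	3'UTR	miRNA-regulation	gain
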