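#genome_length=21000
#or_majority=20950
#or_minority=19500
#repdir_majority=increasing
#repdir_minority=decreasing
gene	start	end	strand	category
ND2	200	1223	majority	ND
COX1	1300	2835	majority	CO
COX2	2900	3587	majority	CO
ATP8	3650	3817	majority	AT
ATP6	3880	4557	majority	AT
COX3	4620	5408	majority	CO
ND3	5470	5823	majority	ND
ND5	5900	7618	minority	ND
ND4	7700	9038	minority	ND
ND4L	9100	9389	minority	ND
ND6	14450	14974	majority	ND
CYTB	15030	16164	majority	CO
ND1	16230	17169	minority	ND
16S	17230	18554	minority	rRNA
12S	18620	19408	minority	rRNA
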