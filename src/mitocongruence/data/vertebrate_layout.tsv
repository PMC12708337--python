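#genome_length=16569
#or_majority=200
#or_minority=5750
#repdir_majority=decreasing
#repdir_minority=increasing
gene	start	end	strand	category
12S	648	1601	majority	rRNA
16S	1671	3229	majority	rRNA
ND1	3307	4262	majority	ND
ND2	4470	5511	majority	ND
COX1	5904	7445	majority	CO
COX2	7586	8269	majority	CO
ATP8	8366	8533	majority	AT
ATP6	8600	9280	majority	AT
COX3	9350	10133	majority	CO
ND3	10200	10545	majority	ND
ND4L	10600	10896	majority	ND
ND4	10950	12327	majority	ND
ND5	12400	14211	majority	ND
ND6	14250	14774	minority	ND
CYTB	14850	15990	majority	CO
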