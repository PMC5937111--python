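network	symbol	degree
up	YWHAZ	1634
up	FN1	1538
up	PPP2R1A	1208
up	CDC37	1158
up	HNRNPA1	1054
up	CAND1	827
up	PABPC1	725
up	MAPRE1	716
up	HNRNPD	703
up	XRCC5	661
up	PSMD2	636
up	FUS	631
up	KPNB1	618
up	DHX9	554
up	EEF1G	538
up	ALB	524
up	NCL	508
up	STAT1	503
up	ACTR2	492
up	CCT7	471
down	HSP90AA1	2019
down	CALM3	1276
down	HSPB1	1038
down	RPL10	992
down	DYNLL1	792
down	ACTG1	681
down	P31947	569
down	RPL9P9	484
down	RAN	479
down	RPS9	450
down	RPL23A	449
down	CANX	427
down	P20618	424
down	EIF3A	412
down	IGHG1	411
down	LMNA	407
down	Q13813	390
down	PHB2	364
down	HNRNPL	351
down	U2AF1	348
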