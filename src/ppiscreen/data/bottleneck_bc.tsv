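network	symbol	bc
up	PDXK	1.0
up	KHC	1.0
up	YWHAZ	0.13462
up	FN1	0.13420
up	CAND1	0.07829
up	HNRNPA1	0.07400
up	CDC37	0.06998
up	GNAI2	0.06835
up	PPP2R1A	0.06310
up	MAPRE1	0.04832
up	FUS	0.04727
up	ENO1	0.04595
up	HNRNPD	0.03861
up	ACTR2	0.03749
up	KPNB1	0.03667
up	PSMD2	0.03599
up	ALB	0.03178
up	HSPD1	0.03167
up	XRCC5	0.03007
up	STAT1	0.02821
down	HSP90AA1	0.20507
down	CALM3	0.13699
down	HSPB1	0.07676
down	ACTG1	0.07472
down	RPL10	0.06626
down	DYNLL1	0.06243
down	C3	0.06131
down	CANX	0.05931
down	SFN	0.04720
down	LMNA	0.04078
down	LGALS3	0.04051
down	A2M	0.03737
down	RAN	0.03283
down	FN1	0.03122
down	PSMB1	0.02739
down	APOA1	0.02707
down	IGHG1	0.02688
down	SOD1	0.02663
down	HNRNPL	0.02442
down	LGALS3BP	0.02210
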