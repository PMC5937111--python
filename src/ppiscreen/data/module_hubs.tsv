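network	module_id	score	n_nodes	n_edges	seed	hubs	hub_bottlenecks
up	Up-1	7.6	65	358	NPM1	HNRNPD,DHX9,FUS,NCL,YWHAZ	HNRNPD,FUS,YWHAZ
up	Up-2	5.8	65	320	HSPA9	KPNB1,XRCC5,CAND1	KPNB1,XRCC5,CAND1
up	Up-3	4.0	52	219	NS	PPP2R1A	PPP2R1A
up	Up-4	3.8	49	115	-	HNRNPA1	HNRNPA1
up	Up-5	3.3	13	44	-	ACTR2	-
down	Down-1	5.87	65	219	UQCRC1	-	-
down	Down-2	4.06	30	80	-	RPL9P9,DYNLL1	DYNLL1
down	Down-3	4.0	15	43	-	-	-
down	Down-4	4.0	10	30	-	CALM3	CALM3
down	Down-5	4.0	18	80	-	ACTG1,HSP90AA1	ACTG1,HSP90AA1
down	Down-6	3.25	17	42	-	PHB2,U2AF1	-
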