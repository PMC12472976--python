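protein_id	dht_percent	activity	n_peptides	Ae	A	W
P06470	26.0300	neprilysin 2 inhibitor	4	0.0137	0.0375	0.3636
P06470	26.0300	antioxidative	2	0.0068	0.0614	0.1111
P06470	26.0300	stimulating	2	0.0068	0.0239	0.2857
P06470	26.0300	antiamnestic	1	0.0034	0.0137	0.2500
P06470	26.0300	lactocepin inhibitor	1	0.0034	0.0137	0.2500
P06472	20.1900	stimulating	2	0.0190	0.1048	0.1818
P06472	20.1900	xaa-pro inhibitor	1	0.0095	0.0095	1.0000
I6SW23	24.4000	dipeptidyl peptidase iv inhibitor	23	0.0308	0.0790	0.3898
I6SW23	24.4000	ace inhibitor	16	0.0214	0.0268	0.8000
I6SW23	24.4000	antioxidative	14	0.0187	0.0348	0.5385
I6SW23	24.4000	calpain 1 inhibitor	13	0.0174	0.0281	0.6190
I6SW23	24.4000	neuropeptide	5	0.0067	0.0201	0.3333
I6SW23	24.4000	antiamnestic	3	0.0040	0.0067	0.6000
I6SW23	24.4000	xaa-pro inhibitor	3	0.0040	0.0120	0.3333
I6SW23	24.4000	neprilysin 2 inhibitor	2	0.0027	0.0161	0.1667
I6SW23	24.4000	stimulating	1	0.0013	0.0067	0.2000
A0A090CXP9	27.1400	antiamnestic	5	0.0102	0.0143	0.7143
A0A090CXP9	27.1400	dipeptidyl peptidase iv inhibitor	4	0.0081	0.0163	0.5000
A0A090CXP9	27.1400	calpain 1 inhibitor	3	0.0061	0.0204	0.3000
A0A090CXP9	27.1400	neprilysin 2 inhibitor	2	0.0041	0.0122	0.3333
A0A090CXP9	27.1400	stimulating	2	0.0041	0.0143	0.2857
A0A090CXP9	27.1400	xaa-pro inhibitor	2	0.0041	0.0163	0.2500
A0A090CXP9	27.1400	ace inhibitor	1	0.0020	0.0061	0.3333
A0A090CXP9	27.1400	antioxidative	1	0.0020	0.0122	0.1667
A0A090CXP9	27.1400	neuropeptide	1	0.0020	0.0163	0.1250
A0A803Q1B3	34.5800	lactocepin inhibitor	5	0.0233	0.0419	0.5556
A0A803Q1B3	34.5800	neprilysin 2 inhibitor	3	0.0140	0.0186	0.7500
A0A803Q1B3	34.5800	neuropeptide	2	0.0093	0.0093	1.0000
A0A803Q1B3	34.5800	stimulating	2	0.0093	0.0233	0.4000
A0A803Q1B3	34.5800	ace inhibitor	1	0.0047	0.0093	0.5000
A0A803Q1B3	34.5800	dipeptidyl peptidase iv inhibitor	1	0.0047	0.0140	0.3333
A0A803Q1B3	34.5800	xaa-pro inhibitor	1	0.0047	0.0047	1.0000
A0A7J6FEU0	31.1600	lactocepin inhibitor	3	0.0075	0.0125	0.6000
A0A7J6FEU0	31.1600	ace inhibitor	2	0.0050	0.0125	0.4000
A0A7J6FEU0	31.1600	dipeptidyl peptidase iv inhibitor	2	0.0050	0.0150	0.3333
A0A7J6FEU0	31.1600	xaa-pro inhibitor	2	0.0050	0.0075	0.6667
A0A7J6FEU0	31.1600	antioxidative	1	0.0025	0.0050	0.5000
A0A7J6FEU0	31.1600	neuropeptide	1	0.0025	0.0075	0.3333
A0A7J6FEU0	31.1600	stimulating	1	0.0025	0.0025	1.0000
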