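gene	comparison	group	mean	sd	n	printed_fc	printed_p
SLC7A2	sbt_vs_hgsoc	SBT	65.35	16.00	4	32.84	2.00e-6
SLC7A2	sbt_vs_hgsoc	HGSOC	1.99	2.09	7	32.84	2.00e-6
PIFO	sbt_vs_hgsoc	SBT	55	35.4	4	28.95	2.53e-3
PIFO	sbt_vs_hgsoc	HGSOC	1.9	1.44	7	28.95	2.53e-3
AFF2	sbt_vs_hgsoc	SBT	3.2	2.24	4	13.33	7.12e-3
AFF2	sbt_vs_hgsoc	HGSOC	0.24	0.53	7	13.33	7.12e-3
HES2	sbt_vs_hgsoc	SBT	5.1	2.44	4	8.64	8.24e-4
HES2	sbt_vs_hgsoc	HGSOC	0.59	0.49	7	8.64	8.24e-4
BBS12	sbt_vs_hgsoc	SBT	4.11	1.16	4	5.96	5.90e-5
BBS12	sbt_vs_hgsoc	HGSOC	0.69	0.47	7	5.96	5.90e-5
RPL12	sbt_vs_hgsoc	SBT	1565.46	698.27	4	5.18	1.07e-3
RPL12	sbt_vs_hgsoc	HGSOC	301.98	168.7	7	5.18	1.07e-3
RPL7A	sbt_vs_hgsoc	SBT	227.97	89.21	4	5.01	6.98e-4
RPL7A	sbt_vs_hgsoc	HGSOC	45.48	31.97	7	5.01	6.98e-4
RPS15	sbt_vs_hgsoc	SBT	3218.63	1563.63	4	4.54	3.22e-3
RPS15	sbt_vs_hgsoc	HGSOC	708.2	547.09	7	4.54	3.22e-3
RPS12	sbt_vs_hgsoc	SBT	3056.61	1034.17	4	4.32	1.04e-3
RPS12	sbt_vs_hgsoc	HGSOC	708.02	630.41	7	4.32	1.04e-3
MAFB	sbt_vs_hgsoc	SBT	5.78	2.56	4	-3.64	7.89e-2
MAFB	sbt_vs_hgsoc	HGSOC	21.04	14.94	7	-3.64	7.89e-2
CRABP2	sbt_vs_hgsoc	SBT	20.13	19.77	4	-5.95	5.59e-2
CRABP2	sbt_vs_hgsoc	HGSOC	119.77	87.65	7	-5.95	5.59e-2
TSPAN1	stage2_vs_stage3	STAGE2	94.34	22.3	3	17.55	5.20e-4
TSPAN1	stage2_vs_stage3	STAGE3	5.38	5.46	4	17.55	5.20e-4
ANK1	stage2_vs_stage3	STAGE2	0.46	0.18	3	10.18	6.61e-3
ANK1	stage2_vs_stage3	STAGE3	0.04	0.06	4	10.18	6.61e-3
SERPINE2	stage2_vs_stage3	STAGE2	68.45	45.04	3	9.18	3.98e-2
SERPINE2	stage2_vs_stage3	STAGE3	7.46	6.57	4	9.18	3.98e-2
SYNPO	stage2_vs_stage3	STAGE2	46.57	20.07	3	8.89	9.24e-3
SYNPO	stage2_vs_stage3	STAGE3	5.24	4.47	4	8.89	9.24e-3
PDGFC	stage2_vs_stage3	STAGE2	30	18.76	3	7.95	3.42e-2
PDGFC	stage2_vs_stage3	STAGE3	3.77	0.85	4	7.95	3.42e-2
NQO1	stage2_vs_stage3	STAGE2	20.81	9.36	3	7.45	1.14e-2
NQO1	stage2_vs_stage3	STAGE3	2.79	1.59	4	7.45	1.14e-2
CA12	stage2_vs_stage3	STAGE2	30.59	8.42	3	6.94	2.25e-3
CA12	stage2_vs_stage3	STAGE3	4.41	3.49	4	6.94	2.25e-3
PPP1R14C	stage2_vs_stage3	STAGE2	4.32	1.04	3	6.86	8.60e-4
PPP1R14C	stage2_vs_stage3	STAGE3	0.63	0.23	4	6.86	8.60e-4
TMEM30B	stage2_vs_stage3	STAGE2	14.47	4.55	3	6.59	2.96e-3
TMEM30B	stage2_vs_stage3	STAGE3	2.2	1.0	4	6.59	2.96e-3
PGK1	stage2_vs_stage3	STAGE2	147.96	70.15	3	5.85	1.62e-2
PGK1	stage2_vs_stage3	STAGE3	25.3	10.29	4	5.85	1.62e-2
DNAJB9	stage2_vs_stage3	STAGE2	13.32	8.54	3	5.45	4.70e-2
DNAJB9	stage2_vs_stage3	STAGE3	2.45	0.76	4	5.45	4.70e-2
CLIC1	stage2_vs_stage3	STAGE2	236.93	57.24	3	4.87	1.08e-3
CLIC1	stage2_vs_stage3	STAGE3	48.63	6.54	4	4.87	1.08e-3
ECE1	stage2_vs_stage3	STAGE2	25.1	4.53	3	4.42	1.00e-3
ECE1	stage2_vs_stage3	STAGE3	5.67	3.03	4	4.42	1.00e-3
ENPP4	stage2_vs_stage3	STAGE2	3.17	0.88	3	4.26	3.71e-3
ENPP4	stage2_vs_stage3	STAGE3	0.74	0.35	4	4.26	3.71e-3
ZDHHC7	stage2_vs_stage3	STAGE2	26.42	14.78	3	4.18	4.02e-2
ZDHHC7	stage2_vs_stage3	STAGE3	6.32	2.57	4	4.18	4.02e-2
GCLC	stage2_vs_stage3	STAGE2	9.83	3.68	3	4.11	9.78e-3
GCLC	stage2_vs_stage3	STAGE3	2.39	0.75	4	4.11	9.78e-3
CHST15	stage2_vs_stage3	STAGE2	13.95	0.82	3	3.90	9.00e-5
CHST15	stage2_vs_stage3	STAGE3	3.57	1.39	4	3.90	9.00e-5
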