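# Per-environment mean GNPP (grains) of F- and M-genotype carriers for the 19
# candidate grain-number genes with parental protein differences in the
# Luohui 9 (indica, M) x RPY geng (japonica, F) RIL population, over five crop
# seasons, with the published win-count score for each parental genotype.
gene	genotype	HN19	EZ18	EZ17	LS17	EZ16	score
Gn1a	F	182.6497	173.4107	167.1413	152.6666	212.2488	0
Gn1a	M	213.6251	209.3672	201.3538	194.33	266.876	5
NOG1	F	216.5889	213.6555	209.3696	191.0993	261.7751	3
NOG1	M	209.5623	204.0087	194.7091	192.5892	266.6108	2
PYL1	F	214.8368	212.1481	208.8955	197.772	267.9565	5
PYL1	M	211.2413	204.1541	192.9816	188.7112	262.2566	0
LAX1	F	217.2252	214.2353	210.1405	199.207	270.9662	5
LAX1	M	209.5813	202.1089	192.1287	187.8076	261.0606	0
LP	F	222.9414	202.7627	200.4978	204.8714	260.9552	2
LP	M	213.5856	211.2246	202.819	192.9035	268.4735	3
PYL4	F	198.6192	185.3971	171.8941	160.8207	219.5586	0
PYL4	M	210.525	209.27	200.3168	192.4851	265.109	5
OSH1	F	212.5358	222.7958	191.7582	199.8374	289.2342	4
OSH1	M	211.9244	203.0429	200.4007	189.2127	255.0527	1
DST	F	201.8318	200.084	187.2243	187.9039	234.3329	0
DST	M	219.2916	211.2264	207.4977	196.3835	275.7076	5
GNP1	F	201.8206	199.0928	191.335	192.5	259.8899	0
GNP1	M	217.3728	211.268	204.5793	192.7047	266.2327	5
An-1	F	209.6562	215.0945	202.7716	188.6553	260.9996	2
An-1	M	213.6572	200.3582	199.252	198.3246	268.3011	3
LAX2	F	212.1621	210.6081	200.55	189.7581	251.7476	3
LAX2	M	211.6038	206.166	199.4247	193.7761	274.4033	2
APO1	F	208.4567	200.882	198.3117	195.7946	246.0994	1
APO1	M	213.6812	208.9489	200.5811	191.586	268.7792	4
DTH7	F	216.7544	203.4692	219.8124	200.7108	274.3199	4
DTH7	M	211.679	207.5063	198.7814	191.6447	263.6816	1
DTH8	F	219.7284	210.7304	206.7825	196.22	271.8351	5
DTH8	M	209.1165	206.4734	196.9023	190.8444	262.2673	0
PAY1	F	218.0417	214.4899	214.4749	192.9009	278.6728	4
PAY1	M	212.2218	207.3872	196.8358	193.6027	263.799	1
GAD1	F	213.9167	210.7948	204.68	192.4931	261.6666	3
GAD1	M	211.1683	207.3715	196.0528	194.2355	262.2458	2
DEP1	F	211.652	220.5395	205.0621	226.2993	266.4615	4
DEP1	M	212.3448	206.3899	199.034	188.2502	263.9062	1
TAW1	F	212.9674	192.356	187.9528	198.0376	253.4211	2
TAW1	M	212.3691	210.8745	203.1138	191.4399	267.4437	3
SP1	F	217.9557	219.8128	206.507	199.3304	278.6635	5
SP1	M	209.8068	203.1178	194.7337	188.4645	257.744	0
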