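focal	closest	support	intra	inter	ratio	pid_strict_mean	pid_strict_low	pid_strict_high	pid_liberal_mean	pid_liberal_low	pid_liberal_high	av_mrca_tips
B. dichotomus	M. gouazoubira	100	0.003	0.156	0.02	0.92	0.80	1.0	0.98	0.87	1.0	0.0025
H. antisensis	H. bisulcus	NA	NA	0.069	NA	NA	NA	NA	0.96	0.83	1.0	NA
H. bisulcus	H. antisensis	100	0.002	0.069	0.03	0.57	0.43	0.72	0.96	0.81	1.0	0.0011
americana group 1	M. temama	<50	0.050	0.090	0.56	0.83	0.77	0.88	0.96	0.93	0.98	0.0341
americana group 2	hemionus group	<50	0.036	0.093	0.39	0.75	0.65	0.86	0.91	0.85	0.97	0.0247
M. chunyi	M. gouazoubira	NA	NA	0.046	NA	NA	NA	NA	0.96	0.83	1.0	NA
M. gouazoubira	M. chunyi	61	0.015	0.046	0.32	0.87	0.80	0.94	0.96	0.92	1.0	0.0107
M. nemorivaga	americana group 2	100	0.069	0.177	0.39	0.78	0.70	0.87	0.93	0.88	0.98	0.0749
M. pandora	columbianus group	100	0.002	0.111	0.02	0.78	0.61	0.96	1.00	0.85	1.0	0.0013
M. rufina	americana group 2	93	0.041	0.130	0.32	0.79	0.69	0.90	0.92	0.86	0.99	0.0449
M. temama	americana group 1	99	0.016	0.090	0.18	0.88	0.80	0.97	0.96	0.91	1.0	0.0270
hemionus group	americana group 2	<50	0.016	0.093	0.17	0.94	0.88	0.99	0.98	0.95	1.0	0.0246
columbianus group	hemionus group	100	0.006	0.097	0.06	0.97	0.92	1.0	0.99	0.97	1.0	0.0040
Oz. bezoarticus	M. gouazoubira	100	0.011	0.138	0.08	0.96	0.89	1.0	0.99	0.95	1.0	0.0111
P. mephistophiles	Oz. bezoarticus	NA	NA	0.160	NA	NA	NA	NA	0.96	0.83	1.0	NA
P. puda	Oz. bezoarticus	100	0.004	0.173	0.02	0.97	0.89	1.0	1.00	0.95	1.0	0.0044
R. tarandus	americana group 2	100	0.010	0.213	0.05	0.98	0.93	1.0	1.00	0.97	1.0	0.0071
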