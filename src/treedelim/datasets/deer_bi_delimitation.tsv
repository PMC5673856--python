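focal	closest	support	intra	inter	ratio	pid_strict_mean	pid_strict_low	pid_strict_high	pid_liberal_mean	pid_liberal_low	pid_liberal_high	av_mrca_tips
B. dichotomus	M. gouazoubira	1.00	0.065	2.014	0.03	0.91	0.79	1.0	0.98	0.87	1.0	0.0352
H. antisensis	H. bisulcus	NA	NA	0.906	NA	NA	NA	NA	0.96	0.83	1.0	NA
H. bisulcus	H. antisensis	1.00	0.047	0.906	0.05	0.56	0.41	0.71	0.95	0.80	1.0	0.0236
americana group 1	M. temama	0.95	0.688	1.248	0.55	0.83	0.78	0.88	0.96	0.93	0.98	0.4722
americana group 2	M. temama	0.89	0.509	1.334	0.38	0.76	0.65	0.86	0.91	0.85	0.98	0.3445
M. chunyi	M. gouazoubira	NA	NA	0.639	NA	NA	NA	NA	0.96	0.83	1.0	NA
M. gouazoubira	M. chunyi	0.95	0.250	0.639	0.39	0.85	0.78	0.91	0.95	0.91	1.00	0.1888
M. nemorivaga	P. mephistophiles	0.92	0.939	2.198	0.43	0.77	0.68	0.85	0.93	0.87	0.98	0.9906
M. pandora	columbianus group	1.00	0.050	1.437	0.03	0.77	0.59	0.94	0.99	0.84	1.0	0.0305
M. rufina	americana group 2	1.00	0.585	1.794	0.33	0.79	0.68	0.89	0.92	0.86	0.98	0.6342
M. temama	americana group 1	1.00	0.239	1.248	0.19	0.88	0.79	0.96	0.96	0.91	1.0	0.3774
hemionus group	americana group 2	0.92	0.270	1.391	0.19	0.93	0.87	0.98	0.98	0.95	1.0	0.4257
columbianus group	hemionus group	1.00	0.117	1.416	0.08	0.96	0.91	1.0	0.99	0.96	1.0	0.0617
Oz. bezoarticus	M. gouazoubira	1.00	0.190	1.885	NA	0.95	0.88	1.0	0.98	0.94	1.0	0.1755
P. mephistophiles	americana group 2	NA	NA	1.921	0.00	NA	NA	NA	0.96	0.83	1.0	NA
P. puda	Oz. bezoarticus	1.00	0.084	2.063	0.04	0.96	0.88	1.0	1.00	0.94	1.0	0.0454
R. tarandus	americana group 2	1.00	0.179	2.658	0.07	0.97	0.92	1.0	0.99	0.96	1.0	0.1416
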