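group	B. dichotomus	H. antisensis	H. bisulcus	americana group 1	americana group 2	M. chunyi	M. gouazoubira	M. nemorivaga	M. pandora	M. rufina	M. temama	columbianus group	hemionus group	Oz. bezoarticus	P. mephistophiles	P. puda	R. tarandus
B. dichotomus	0.3	4.4	7.6	9.8	10.3	7.1	7.2	6.9	10.9	8.0	10.0	8.4	9.0	8.2	5.2	14.6	9.5
H. antisensis	4.2	NA	3.0	8.8	9.3	2.5	2.6	5.8	9.9	7.3	8.8	7.4	8.0	8.3	4.2	12.5	6.6
H. bisulcus	7.1	2.9	0.8	8.3	9.9	3.8	5.8	5.9	11.4	5.6	8.3	10.1	9.5	7.8	7.4	10.2	5.6
americana group 1	9.1	8.2	7.7	2.8	3.7	7.2	9.1	8.9	4.3	4.8	3.3	6.6	4.8	10.3	7.8	10.1	6.9
americana group 2	9.5	8.5	9.1	3.8	3.2	7.2	8.8	9.0	4.3	5.2	3.9	6.7	5.8	10.6	8.3	11.1	8.6
M. chunyi	6.7	2.5	3.7	6.7	6.8	NA	1.8	6.3	7.0	4.7	6.0	7.5	7.1	9.3	7.0	11.7	7.6
M. gouazoubira	6.8	2.6	5.4	8.4	8.1	1.8	0.5	7.1	9.0	6.5	8.0	7.7	9.1	11.4	7.1	13.4	9.6
M. nemorivaga	6.5	5.5	5.6	8.2	8.3	5.9	6.6	3.6	9.6	5.3	8.0	7.8	9.4	8.1	6.6	12.2	9.2
M. pandora	10.0	9.0	10.2	4.1	4.1	6.6	8.3	8.8	0.0	6.3	5.2	7.5	6.2	13.3	8.8	12.9	9.7
M. rufina	7.5	6.8	5.3	4.6	5.0	4.5	6.1	5.1	5.9	1.5	3.7	6.7	6.4	8.3	6.3	8.4	6.7
M. temama	9.3	8.2	7.8	3.2	3.8	5.7	7.5	7.5	5.0	3.6	0.7	5.6	4.6	8.7	8.0	9.9	6.8
columbianus group	7.9	7.0	9.2	6.2	6.3	7.0	7.2	7.2	6.9	6.3	5.4	2.2	6.6	12.3	6.3	11.9	9.1
hemionus group	8.4	7.5	8.7	4.5	5.5	6.7	8.4	8.7	5.8	6.0	4.4	6.2	0.2	11.3	7.0	11.0	7.9
Oz. bezoarticus	7.7	7.7	7.2	9.5	9.7	8.5	10.3	7.5	11.8	7.7	8.0	11.1	10.3	0.7	9.2	15.2	7.8
P. mephistophiles	5.1	4.1	7.0	7.3	7.7	6.6	6.7	6.2	8.2	5.9	7.5	6.0	6.7	8.5	NA	10.4	5.8
P. puda	13.1	11.3	9.4	9.4	10.2	10.7	12.0	11.1	11.7	7.9	9.2	10.8	10.1	13.5	9.7	0.4	9.8
R. tarandus	8.7	6.1	5.3	6.5	7.9	7.1	8.7	8.4	8.9	6.2	6.4	8.3	7.4	7.3	5.5	9.1	0.8
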