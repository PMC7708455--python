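hex	hexnac	fuc	neuac
5	2	0	0
6	2	0	0
7	2	0	0
8	2	0	0
9	2	0	0
3	2	1	0
3	4	1	0
4	3	1	0
4	4	1	0
5	4	1	0
5	4	2	0
5	5	1	0
6	5	1	0
6	5	2	0
7	6	1	0
3	5	1	0
4	5	3	0
4	4	0	1
5	4	0	1
5	4	0	2
6	5	0	1
6	5	0	3
7	6	0	2
3	4	0	1
5	5	0	2
4	4	1	1
5	4	1	1
5	4	1	2
6	5	1	1
6	5	1	3
7	6	2	2
5	5	2	1
3	4	1	1
3	2	0	0
4	2	0	0
3	3	0	0
4	4	0	0
5	4	0	0
6	5	0	0
7	6	0	0
4	3	0	0
6	3	0	0
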