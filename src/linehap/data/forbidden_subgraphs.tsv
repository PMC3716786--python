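# nine minimal forbidden induced subgraphs of line graphs (claw first)
f0	0	1
f0	0	2
f0	0	3
f1	0	2
f1	0	3
f1	0	4
f1	1	2
f1	1	3
f1	1	4
f1	2	3
f2	0	1
f2	0	2
f2	0	3
f2	0	4
f2	1	2
f2	1	3
f2	1	4
f2	2	3
f2	2	4
f3	0	2
f3	0	3
f3	0	4
f3	1	2
f3	1	3
f3	1	5
f3	2	3
f4	0	1
f4	0	3
f4	0	5
f4	1	2
f4	1	3
f4	2	3
f4	2	4
f4	4	5
f5	0	1
f5	0	2
f5	0	3
f5	0	5
f5	1	2
f5	1	3
f5	1	4
f5	2	4
f5	3	5
f6	0	1
f6	0	2
f6	0	3
f6	0	4
f6	1	2
f6	1	3
f6	1	4
f6	2	3
f6	4	5
f7	0	1
f7	0	2
f7	0	3
f7	0	4
f7	0	5
f7	1	2
f7	1	5
f7	2	3
f7	3	4
f7	4	5
f8	0	1
f8	0	2
f8	0	3
f8	0	4
f8	0	5
f8	1	2
f8	1	3
f8	1	4
f8	1	5
f8	2	3
f8	4	5
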