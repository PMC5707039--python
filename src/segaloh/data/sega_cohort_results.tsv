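case	gene	nucleotide_change	maf_percent	mutation_type	protein_change	cn_loh	summary
1	NMI						NMI
2	NMI	TSC1 c.1-7G>A	50	possible-initiator		No	possible mutation, no CN-LOH
3	TSC1	chr9:135700060-135799506del	78	genomic deletion	deletion of exons 6-23	Yes	large del+CN-LOH
4	TSC1	c.1498C>T	71	nonsense	p.R500*	Yes	point+CN-LOH
5	TSC1	c.641_644dupAGAC	93	insertion	p.F216Dfs*3	Yes	point+CN-LOH
6	TSC1	c.2074C>T	39	nonsense	p.R692*	Yes	point+CN-LOH
7	TSC1	c.1525C>T	12	nonsense	p.R509*	No	point no LOH
8	TSC1	c.2699dupA	65	insertion	p.Q901Efs*3	Yes	point+CN-LOH
9	TSC1	c.1802dupC	79	insertion	p.P602Sfs*4	Yes	point+CN-LOH
10	TSC1	c.935dupA	29	nonsense	p.Y312*	Yes	point+CN-LOH
11	TSC1	c.1525C>T	76	nonsense	p.R509*	Yes	point+CN-LOH
12	TSC1	c.2695C>T	70	nonsense	p.Q899*	Yes	point+CN-LOH
13	TSC2	c.4375C>T	50	nonsense	p.R1459*	No	point no LOH
14	TSC2	c.3412C>T	68	nonsense	p.R1138*	Yes	point+CN-LOH
15	TSC2	c.2353C>T	12	nonsense	p.Q785*	Yes	point+CN-LOH
16	TSC2	c.2221-1G>C	55	splice	p.L741_splice	Yes	point+CN-LOH
17	TSC2	c.790_791delCT	30	deletion	p.L264Wfs*73	No	point no LOH
18	TSC2	c.903_922delGGCTCTCTGGGGAGCCCACC	34	deletion	p.W304Ffs*27	Yes	point+CN-LOH
19	TSC2	c.5227_5244delCGGCTCCGCCACATCAAG	72	in-frame deletion	p.R1743_K1748del	Yes	point+CN-LOH
20	TSC2	c.1832G>A	65	missense	p.R611Q	Yes	point+CN-LOH
21	TSC2	c.3526_3527insT	38	insertion	p.P1176fs	Yes	point+CN-LOH
22	TSC2	c.1513C>T	47	nonsense	p.R505*	Yes	point+CN-LOH
23	TSC2	c.3171_3172insA	17	insertion	p.T1059Nfs*109	No	point no LOH
24	TSC2	c.268C>T	75	nonsense	p.Q90*	Yes	point+CN-LOH
25	TSC2	c.2251C>T	63	nonsense	p.R751*	Yes	point+CN-LOH
26	TSC2	c.5227_5244delCGGCTCCGCCACATCAAG	80	in-frame deletion	p.R1743_K1748del	Yes	point+CN-LOH
27	TSC2	c.5168C>A	34	nonsense	p.S1723*	Yes	point+CN-LOH
28	TSC2	c.3599G>C	57	missense	p.R1200P	Yes	point+CN-LOH
29	TSC2	c.1372C>T	32	nonsense	p.R458*	Yes	point+CN-LOH
30	TSC2	c.3814+1G>C	47	splice	p.V1272_splice	No	2 points
30	TSC2	c.1831C>T	15	missense	p.R611W		
31	TSC2	c.412G>T	51	nonsense	p.E138*	No	point no LOH
32	TSC2					Yes	CN-LOH, no point
33	TSC2					Yes	CN-LOH, no point
34	TSC2					Yes	CN-LOH, no point
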