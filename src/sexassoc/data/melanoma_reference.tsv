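# Published sex-stratified melanoma association results for the 16 SNPs
# reported by the Spanish melanoma case-control study: per-sex additive
# odds ratio per minor-allele copy with 95% CI and P value, plus the
# study's sex-differentiated P value. Values are as printed (rounded);
# beta/SE reconstruction from OR/CI therefore carries rounding error.
gene	rsid	chrom	minor_allele	p_f	or_f	ci_low_f	ci_high_f	p_m	or_m	ci_low_m	ci_high_m	p_sexdiff
AP3B1	rs11742673	5	A	0.0020	1.43	1.14	1.80	0.88	0.98	0.75	1.28	0.0210
CDK2/SILV	rs2069398	12	A	3.03E-4	0.47	0.31	0.71	0.06	0.60	0.35	1.03	0.0016
F2RL1	rs2242991	5	G	0.56	0.92	0.68	1.22	0.0076	1.61	1.13	2.29	0.0067
GPR143	rs2521667	X	G	0.46	0.89	0.67	1.20	7.04E-4	1.89	1.30	2.74	7.85E-4
GPR143	rs2732872	X	C	0.78	0.96	0.73	1.27	8.43E-4	1.81	1.27	2.57	0.0052
KIT	rs6554198	4	G	0.46	0.92	0.73	1.15	0.0027	0.67	0.51	0.87	0.07
MYO7A	rs3758708	11	A	0.20	1.30	0.87	1.95	4.12E-4	2.38	1.46	3.90	0.0480
RAB38	rs524121	11	C	0.0086	0.51	0.30	0.85	0.36	1.32	0.73	2.38	0.0210
RGS20	rs6981243	8	C	0.38	0.90	0.71	1.14	0.0021	0.66	0.51	0.86	0.0490
SLC45A2	rs35414	5	T	0.03	0.77	0.61	0.97	0.0018	0.66	0.51	0.85	0.39
SLC45A2	rs35415	5	A	0.03	0.78	0.62	0.97	0.0080	0.70	0.54	0.91	0.35
TYR	rs1042602	11	A	0.35	1.11	0.89	1.40	0.0047	0.68	0.53	0.89	0.0081
TYR	rs12270717	11	C	0.60	1.07	0.82	1.40	0.0032	1.56	1.16	2.09	0.09
TYR	rs17793678	11	T	0.32	1.14	0.88	1.49	0.0036	1.55	1.15	2.08	0.26
TYR	rs2186640	11	G	0.39	0.90	0.71	1.15	9.20E-4	1.57	1.20	2.05	0.0380
TYR	rs5021654	11	C	0.47	0.92	0.72	1.16	2.03E-4	1.66	1.27	2.17	0.0014
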