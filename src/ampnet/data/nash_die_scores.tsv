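genus	z_die_bw	z_die_mb	rank_bw	rank_mb	dist
Acidovorax	-0.45	0.88	20	32	12
Acinetobacter	-0.49	0.64	14	21	7
Actinomyces	1.89	0.88	32	28	4
Akkermansia	-0.35	0.88	26	25	1
Arcobacter	-0.43	-0.58	24	7	17
Bifidobacterium	-0.54	-0.01	11	10	1
Campylobacter	-0.46	0.86	18	23	5
Citrobacter	-0.56	0.88	10	31	21
Clostridium	-0.8	0.09	1	12	11
Weissella	-0.35	0.4	25	18	7
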