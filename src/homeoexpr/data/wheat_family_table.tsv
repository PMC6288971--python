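gene	paralog	genome	chromosome	start_codon	orientation	exon1	intron	exon2	aa	splice_consensus
Esi3-1-A	1	A	4AS	122736187	+/-	83	98	82	54	True
Esi3-1-B	1	B	4BL	424862167	+/+	81	98	84	54	True
Esi3-1-D	1	D	4DL	343061456	+/+	81	95	84	54	True
Esi3-2-A	2	A	4AS	122627489	+/-	81	99	84	54	True
Esi3-2-D	2	D	4DL	343088889	+/+	81	99	84	54	True
Esi3-3-A	3	A	5AL	561693119	+/+	88	140	134	73	True
Esi3-3-B	3	B	5BL	541736786	+/+	88	110	134	73	True
Esi3-3-D	3	D	5DL	444852365	+/+	90	119	132	73	True
Esi3-4-A	4	A	1AS	65759553	+/-	84	161	84	55	True
Esi3-4-B	4	B	1BS	108210663	+/-	84	162	84	55	True
Esi3-4-D	4	D	1DS	66987844	+/-	84	191	84	55	True
Esi3-5-A	5	A	2AS	100129674	+/-	90	93	84	57	True
Esi3-5-B	5	B	2BS	152175965	+/-	90	105	84	57	True
Esi3-5-D	5	D	2DS	100318450	+/-	90	140	84	57	True
Esi3-6-A	6	A	7AL	692509547	+/-	93	110	138	76	True
Esi3-6-B	6	B	7BL	679884026	+/-	96	136	138	77	True
Esi3-6-D	6	D	7DL	600502457	+/-	96	123	138	77	True
Esi3-7-A	7	A	7AS	102537985	+/-	96	109	135	76	True
Esi3-7-B	7	B	7BS	55853830	+/-	99	96	144	79	True
Esi3-7-D	7	D	7DS	100281019	+/-	96	96	132	76	True
Esi3-8-A	8	A	1AS	42505283	+/-	81	95	84	54	True
Esi3-8-B	8	B	1BS	62681663	+/+	81	120	84	54	True
Esi3-8-D	8	D	1DS	42845718	+/-	81	115	84	54	True
Esi3-9-A	9	A	2AL	775064923	+/+	240	170	84	107	True
Esi3-9-B	9	B	2BL	785821555	+/-	318	171	84	133	False
Esi3-9-D	9	D	2DL	649781640	+/-	276	170	84	119	True
Esi3-10-A	10	A	5AL	561688908	+/+	90	141	126	71	True
Esi3-10-B	10	B	5BL	541683185	+/+	90	1111	126	71	True
Esi3-10-D	10	D	5DL	444743823	+/+	90	984	126	71	True
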