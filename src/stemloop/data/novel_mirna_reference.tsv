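miR_name	miR_seq	LM	LP	CG	dG	MFEI	FbA	FbB
bra-miRn1-1-5p	CTATCGGTCTACTCGGTCAGC	21	153	50	-131.5	1.2	19	7
bra-miRn1-1-3p	TGACCGAGTAGACCGATAGTC	21	153	50	-131.5	1.2	87	222
bra-miRn1-2-5p	CTATCGGTCTACTCGGTCAGC	21	153	47	-152.2	1.3	19	7
bra-miRn1-2-3p	TGACCGAGTAGACCGATAGTC	21	153	47	-152.2	1.3	87	222
bra-miRn2-5p	CAACAGTCTCAGGATGGAAAA	21	134	35	-47.6	1	3	12
bra-miRn2-3p	TTTCATCTTAGAGAATGTTGTT	22	134	35	-47.6	1	57	153
bra-miRn3-5p	TACAAAGCTGAAGCTAATTATG	22	141	41	-70.2	0.9	18	56
bra-miRn3-3p	TAATCAGCTCCAGCTATGTACA	22	141	41	-70.2	0.9	145	175
bra-miRn4-5p	GAATGATACTTGGATATGATC	21	147	34.7	-80.3	1.5	14	6
bra-miRn4-3p	TTATATCCAAGTATCATTCCT	21	147	34.7	-80.3	1.5	15	34
bra-miRn5-5p	TTCTAAGCTTTACGGGAAACC	21	201	29	-101.4	1.7	10	11
bra-miRn5-3p	TTTCCCGTAAAGCTTAGAACC	21	201	29	-101.4	1.7	12	7
bra-miRn6-5p	GTCAATTGGTGATAGTAGTTC	21	84	36.7	-38.3	1.2	11	41
bra-miRn6-3p	TCTACTTTCACCAATTGGCCT	21	84	36.7	-38.3	1.2	4	54
bra-miRn7-5p	TTTTGCGTTTCAACTCGGTCC	21	139	38.8	-64	0.9	73	61
bra-miRn7-3p	GCTGAGTTGGAACACAAAATC	21	139	38.8	-64	0.9	19	8
bra-miRn8-5p	AGAGATGTCTGGCTTGCAACA	21	140	44.5	-74.3	1.1	1	3
bra-miRn8-3p	TTGCAAGCCAGACATTTCCTTT	22	140	44.5	-74.3	1.1	5	9
bra-miRn9-5p	TTTGGATTTTGGTCATTGTTG	21	107	32.1	-50.7	1.4	0	2
bra-miRn9-3p	ACAATGAACGAAATCCAAATC	21	107	32.1	-50.7	1.4	4	9
bra-miRn10-1-5p	ACAGGTGGTGGAACAAATATGAGT	24	128	31.8	-52.5	1.3	1	13
bra-miRn10-1-3p	TCATATTAGTTCTACCTCCTGCTG	24	128	31.8	-52.5	1.3	2	7
bra-miRn10-2-5p	ACAGGTGGTGGAACAAATATGAGT	24	130	31.6	-44.4	1	1	13
bra-miRn10-2-3p	TCATATTAGTTCTACCTCCTGCTG	24	130	31.6	-44.4	1	2	7
bra-miRn11-5p	TGAGTCTCTCACCAGTCTTTCAC	23	117	34.1	-59.3	1.4	2	2
bra-miRn11-3p	GAGAGACTCTGAAAGACTCACC	22	117	34.1	-59.3	1.4	8	5
bra-miRn12-5p	TGTAATTGCGGGGTTCTAAGC	21	204	29.1	-103.6	1.7	7	9
bra-miRn12-3p	TTAGAAACCTGCAATTATATA	21	204	29.1	-103.6	1.7	3	3
bra-miRn13-5p	ACTATGCAATTGTGAACAAAC	21	128	29.5	-56.4	1.3	2	3
bra-miRn13-3p	TTATTCACAACTGCATAATTC	21	128	29.5	-56.4	1.3	2	0
bra-miRn14-5p	GGGAGCCAGGGAAGAGGCAGT	21	165	41.7	-66	0.9	0	2
bra-miRn14-3p	TGCTTGTTCCCTGTCTCTCTC	21	165	41.7	-66	0.9	4	1
bra-miRn15-5p	ACCCGTCTCTTAATTTTTAAC	21	161	31.7	-59.4	1.1	19	32
bra-miRn15-3p	TAAAAGTTAAGAGACAAGTTA	21	161	31.7	-59.4	1.1	0	1
bra-miRn16-5p	ATAAAACGATTACACAGCTCGGTC	24	230	42.1	-209.8	2.1	1	1
bra-miRn16-3p	CGAGCTGTGTAATCGTTTTGTTA	23	230	42.1	-209.8	2.1	1	0
bra-miRn17-5p	TCTCGTTCTCTCGTTTCAGCT	21	114	39.6	-56.6	1	0	3
bra-miRn17-3p	CTGAAGCTAGTGAAAGAGAGA	21	114	39.6	-56.6	1	0	2
bra-miRn18-5p	TTGTTGACAAATACTTAGGCTC	22	154	33.5	-121.6	1.7	3	7
bra-miRn18-3p	GAGCCTAAGTATTTGTCAACAATG	24	154	33.5	-121.6	1.7	0	7
bra-miRn19-5p	TAAACAACACATATACTTTGC	21	132	37	-89.6	1.8	0	2
bra-miRn19-3p	AAACTATATGTGTTGCTTAGA	21	132	37	-89.6	1.8	1	0
bra-miRn20-5p	AAGAACTCGTCTCTTAACTTTTAA	24	177	30.7	-86.7	1.2	1	5
bra-miRn20-3p	AAACTAAGAGATGAATTCTTAC	22	177	30.7	-86.7	1.2	1	1
bra-miRn21-5p	NGCGGATATCTTAGGATGAGGT	22	144	28.7	-55.8	1.3	0	1
bra-miRn21-3p	TCATCGTAAGAGATCTGCATT	21	144	28.7	-55.8	1.3	0	1
bra-miRn22-5p	TGAGTTATCATTGGTCTTGTG	21	186	28.1	-94.6	1.8	0	1
bra-miRn22-3p	ACACAGGAACAATACTAACTCATT	24	186	28.1	-94.6	1.8	2664	4123
bra-miRn23-5p	CTTTGTCTATCGTTTGGAAAAG	22	101	37.4	-37	0.9	25	95
bra-miRn23-3p	TTTCCAAATGTAGACAAAGCT	21	101	37.4	-37	0.9	0	1
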