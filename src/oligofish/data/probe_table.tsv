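No.	Probe	Sequence	Length	Position in consensus	Tm (°C)	Modification
1	18SrDNA_UniOP_1	CCGGAGAGGGAGCCTGAGAAACGGCTAC	28	386…413	49.2	5′-Cy3
2	18SrDNA_UniOP_2	ATCCAAGGAAGGCAGCAGGCGCGCAA	26	417…442	50.9	5′-Cy3
3	18SrDNA_UniOP_3	GGGCAAGTCTGGTGCCAGCAGCCGCGGT	28	555…582	53.4	5′-Cy3
4	18SrDNA_UniOP_4	TCGAAGACGATYAGATACCGTCSTAGT	27	994…1020	40.4–43.4	5′-Cy3
5	18SrDNA_UniOP_5	CTGAAACTTAAAGGAATTGACGGAAGG	27	1133…1159	40	5′-Cy3
6	18SrDNA_UniOP_6	GGAGCCTGCGGCTTAATTTGACTCAAC	27	1174…1200	45.0	5′-Cy3
7	18SrDNA_UniOP_7	GGTGGTGCATGGCCGTTCTTAGTTGGTGG	29	1272…1300	47.1	5′-Cy3
8	18SrDNA_UniOP_8	ACGTCCCTGCCCTTTGTACACACCGCCCGTC	31	1622…1652	51.0	5′-Cy3
9	5.8SrDNA_UniOP_1	AAYGACTCTCGGCAACGGATATCTMG	26	16…41	42.0–44.9	5′-Cy3
10	5.8SrDNA_UniOP_2	CWYGCATCGATGAAGAACGTAGCRA	25	45…69	42.2–45.2	5′-Cy3
11	5.8SrDNA_UniOP_3	GCGATACTTGGTGTGAATTGCAGAATC	27	73…99	42.0	5′-Cy3
12	5.8SrDNA_UniOP_4	GTGAACCATCGAGTYTTTGAACGCAAGT	28	102…129	43.4	5′-Cy3
13	5SrDNA_ang_1	GGATGCGATCATACCAGCACTAAAGCACCG	30	1…30	48.2	5′-Alexa Fluor 488
14	5SrDNA_gym_1	GRGTGCGATMATACCASCGYTWRYGYA	27	1…27	38.4–48.0	5′-Alexa Fluor 488
15	5SrDNA_cranial_1	GYYTAYRGCCAYACCACCCTGRRHRCG	27	1…27	37.8–48.3	5′-Alexa Fluor 488
16	5SrDNA_ang_2	CCCATCAGAACTCCGAAGTTAAGCGTGCT	29	34…62	47.4	5′-Alexa Fluor 488
17	5SrDNA_gym_2	ATCCSATCAGAACTCCGYARTTAAGCR	27	32…58	39.7–45.6	5′-Alexa Fluor 488
18	5SrDNA_cranial_2	GATCTCGTCYGATCTCGGAAGCTAAGC	27	31…57	45.6–46.8	5′-Alexa Fluor 488
19	5SrDNA_ang_3	GCGAGAGTAGTACTAGGATGGGTG	24	66…89	40.7	5′-Alexa Fluor 488
20	5SrDNA_gym_3	TTGGGYYRGAGTAGTACTRGGATGGGT	27	62…88	38.4–42.2	5′-Alexa Fluor 488
21	5SrDNA_cranial_3	GTCGGGCCYGGTYAGTACTTGGATGGG	27	61…87	44.4–46.6	5′-Alexa Fluor 488
22	5SrDNA_ang_4	CCTGGGAAGTMCTCGTGTTGCAYYCC	26	94…119	40.7–42.2	5′-Alexa Fluor 488
23	5SrDNA_gym_4	CTCYYGGGAAGTCCYRRTRTYGCACCC	27	92…118	41.9–44.8	5′-Alexa Fluor 488
24	5SrDNA_cranial_4	CYGCCTGGGAATACCRGGTGYYGTARG	27	91…117	41.9–48.6	5′-Alexa Fluor 488
25	Tel_UniOP_Arabidopsis	TTTAGGGTTTAGGGTTTAGGGTTTAGGGT	29	na	40.27	ATTO425
26	Pgms1	ACATTCTTGATACATTCTTGATACATTCTT	30	na	38.13	5′-Cy3
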