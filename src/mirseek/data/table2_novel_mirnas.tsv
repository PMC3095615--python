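id	location	orientation	abundance	sequence	length_nt	hairpin_length_nt	mfe	class	star
1	scaffold03050:42052.42075	+	1	AATTAAGAATATAACAACATTTAA	24	230	-67.60	A	AAATGTTGCTATATACTTAATTAT(1)
2	scaffold04026:144.163	+	1	CCTCATTTTGGTCAACCGGC	20	155	-49.69	A	ATCGGTTTACGCACTAATG(1)
3	scaffold03577:144799.144819	+	10	TGGTCGTCCTGAAAACACATG	21	134	-42.00	A	TGTGTTCTCAGGTCGCCCCTG(8)
4_1	scaffold01087:76.96	+	6	GAAGGCTGTGATGATTATTGA	21	223	-97.90	B	NO
4_2	scaffold04146:100.120	+	6	GAAGGCTGTGATGATTATTGA	21	225	-94.50	B	NO
5	scaffold02633:580263.580284	-	10	TTCCAAGTCCACCCATGCCCGC	22	185	-72.10	B	NO
6	scaffold01374:173181.173204	-	59	ATTGAGCTATGCTCGCTTTGGCAA	24	196	-91.00	B	NO
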