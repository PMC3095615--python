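family	conserved	size_min	size_max	five_prime_end
miR156	1	20	23	U (68%)
miR159	1	19	23	U (77%)
miR160	1	20	21	U (100%)
miR164	1	20	21	U (67%)
miR165	1	21	21	U (100%)
miR166	1	21	22	U (100%)
miR167	1	21	23	U (87%)
miR168	1	21	22	U (75%)
miR169	1	21	23	U (75%)
miR171	1	19	23	U (65%)
miR172	1	19	21	A/G (50%)
miR319	1	20	21	U (100%)
miR390	1	19	21	A (75%)
miR393	1	21	23	U (100%)
miR396	1	21	22	U (100%)
miR397	1	21	21	C (50%)
miR398	1	20	21	U (100%)
miR399	1	21	21	U (100%)
miR408	1	21	22	U (66%)
miR170	0	21	22	U (100%)
miR827	0	22	22	U (100%)
miR858	0	22	22	U (100%)
miR894	0	20	21	G/C (50%)
miR1030	0	19	19	C (100%)
miR2950	0	21	22	U (100%)
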