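# Reference benchmark: 17 experimentally characterized MetaCyc pathways
# projected from E. coli (template) onto B. subtilis (target).
# Percentages on the 0-100 scale; O|P|X|E = genes recruited via operon,
# protein-protein interaction, co-evolution, co-expression.
pathway	n_template	n_target_gold	n_initial	precision_initial	recall_initial	O	P	X	E	n_final	precision_final	recall_final
Chorismate biosynthesis I	11	8	6	100	75	0	1	0	0	7	27	87.5
D-glucuronate degradation	5	4	2	50	50	1	0	0	0	3	13	75
Galacturonate and glucuronate catabolism	7	6	4	67	67	1	0	0	0	5	22	83
Peptidoglycan biosynthesis I	11	14	10	100	71	0	2	0	0	12	41	86
Thiamin biosynthesis I	14	6	6	60	100	0	0	0	0	6	16	100
Sulfate reduction I	8	8	5	71	62.5	3	0	0	0	8	12.5	100
Histidine biosynthesis	8	7	6	75	87	0	0	0	0	6	33	87
1,4-dihydroxy-2-naphthoate biosynthesis I	6	7	5	100	71	1	0	0	0	6	75	87
Flavin biosynthesis I	6	6	4	100	67	1	0	0	0	5	24	83
Tryptophan biosynthesis	5	7	5	100	71	1	0	0	0	6	50	87
NAD biosynthesis I	5	5	5	100	100	0	0	0	0	5	26	100
5-aminoimidazole Ribonucleotide biosynthesis I	5	6	5	100	83	1	0	0	0	6	35.2	100
Biotin-carboxyl carrier protein assembly	5	5	5	100	100	0	0	0	0	5	15.6	100
Pentose phosphate pathway	3	4	3	100	75	0	0	0	0	3	37.5	75
Heme biosynthesis from uroporphyrinogen-III	4	4	3	100	75	1	0	0	0	4	18	100
2-ketoglutarate dehydrogenase complex	3	5	3	100	60	0	0	0	0	3	13	60
2,3-dihydroxybenzoate biosynthesis	3	4	3	100	75	0	0	0	0	3	23	75
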