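# MCA paints on the L. concava karyotype, one row per painted block,
# ordered pter->qter per LCO chromosome. "or" alternatives as in the ACU
# map (MCA 2 on LCO 3pt/7q, MCA 4 on LCO 6q/12). MCA 9 is intact on
# LCO 9 but rearranged by inversion (flag). MCA 13 sits interstitially in
# LCO 8q, distal to the centromere and proximal to the MCA 3q block.
target_species	target_chrom	order_index	target_region	source_species	source_region	alternatives	flags
LCO	1	1	p	MCA	10
LCO	1	2	qp	MCA	11
LCO	1	3	qt	MCA	14
LCO	2	1	p	MCA	5q
LCO	2	2	qp	MCA	6p
LCO	2	3	qt	MCA	6q
LCO	3	1	pt	MCA	2p	2q
LCO	3	2	pp	MCA	18
LCO	3	3	q	MCA	1q
LCO	4	1	p	MCA	1p
LCO	4	2	q	MCA	12
LCO	5	1	p	MCA	3p
LCO	5	2	qp	MCA	17
LCO	5	3	qt	MCA	7
LCO	6	1	p	MCA	13
LCO	6	2	q	MCA	4p	4q
LCO	7	1	p	MCA	15
LCO	7	2	q	MCA	2q	2p
LCO	8	1	p	MCA	7
LCO	8	2	qi	MCA	13
LCO	8	3	qd	MCA	3q
LCO	9	1	whole	MCA	9		inverted
LCO	10	1	whole	MCA	8
LCO	11	1	p/qp	MCA	16
LCO	11	2	qt	MCA	19
LCO	12	1	whole	MCA	4q	4p
LCO	13	1	whole	MCA	5p
LCO	X	1	whole	MCA	X
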