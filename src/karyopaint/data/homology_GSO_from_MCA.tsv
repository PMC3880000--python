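# MCA paints on the G. soricina karyotype, one row per painted block,
# ordered pter->qter per GSO chromosome (homology-table arm assignments
# with block boundaries from the painting figure: the MCA 5q homology on
# GSO 1p appears as two signals separated by unlabeled heterochromatin).
# GSO 15 carries the NOR-bearing arm as an explicit gap row.
target_species	target_chrom	order_index	target_region	source_species	source_region	alternatives	flags
GSO	1	1	pt	MCA	5q
GSO	1	2	pi	-	-
GSO	1	3	pp	MCA	5q
GSO	1	4	q	MCA	10
GSO	2	1	p	MCA	12
GSO	2	2	q	MCA	2q
GSO	3	1	p/qp	MCA	13
GSO	3	2	qd	MCA	3q
GSO	4	1	p	MCA	14
GSO	4	2	q	MCA	1q
GSO	5	1	p	MCA	3p
GSO	5	2	q	MCA	11
GSO	6	1	p	MCA	2p
GSO	6	2	q	MCA	1p
GSO	7	1	p	MCA	4p
GSO	7	2	q	MCA	4q
GSO	8	1	p/qp	MCA	9
GSO	8	2	qt	MCA	17
GSO	9	1	p	MCA	6p
GSO	9	2	q	MCA	6q
GSO	10	1	whole	MCA	7
GSO	11	1	whole	MCA	8
GSO	12	1	p/qp	MCA	18
GSO	12	2	qt	MCA	5p
GSO	13	1	whole	MCA	16
GSO	14	1	whole	MCA	15
GSO	15	1	p	-	-		NOR-adjacent
GSO	15	2	q	MCA	19
GSO	X	1	whole	MCA	X
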