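# MCA paints on the A. cultrata karyotype, one row per painted block,
# ordered pter->qter per ACU chromosome. "or" alternatives record
# whole-chromosome paints whose arm assignment between two signals is
# unresolved (MCA 2 on ACU 7/9, MCA 3 on ACU 5q/2qt, MCA 4 on ACU
# 4qd/13, MCA 6 on ACU 3p/2pt); the source chromosome is certain.
# ACU 4 carries its small heterochromatic short arm as a gap row.
target_species	target_chrom	order_index	target_region	source_species	source_region	alternatives	flags
ACU	1	1	pt	MCA	12
ACU	1	2	pp	MCA	5q
ACU	1	3	qp	MCA	16
ACU	1	4	qi	MCA	9
ACU	1	5	qi	MCA	17
ACU	1	6	qt	MCA	14
ACU	2	1	pt	MCA	6q	6p
ACU	2	2	qp	MCA	13
ACU	2	3	qt	MCA	3q	3p
ACU	3	1	p	MCA	6p	6q
ACU	3	2	q	MCA	1q
ACU	4	1	p	-	-
ACU	4	2	qp	MCA	1p
ACU	4	3	qd	MCA	4p	4q
ACU	5	1	p	MCA	5p
ACU	5	2	qp	MCA	18
ACU	5	3	qi	MCA	13
ACU	5	4	qd	MCA	3p	3q
ACU	6	1	pt	MCA	16
ACU	6	2	pp	MCA	19
ACU	6	3	qp	MCA	18
ACU	6	4	qd	MCA	15
ACU	7	1	whole	MCA	2p	2q
ACU	8	1	whole	MCA	10		bi-armed
ACU	9	1	whole	MCA	2q	2p
ACU	10	1	whole	MCA	7
ACU	11	1	whole	MCA	11		bi-armed
ACU	12	1	whole	MCA	8
ACU	13	1	whole	MCA	4q	4p
ACU	14	1	whole	MCA	9
ACU	X	1	whole	MCA	X
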