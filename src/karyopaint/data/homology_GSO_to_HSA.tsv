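# Human (HSA) chromosome segments on the G. soricina karyotype: the ECU
# column of the homology table transferred to GSO coordinates through the
# MCA paints, refined by the recently detected segments GSO 3qp: HSA 13;
# GSO 8qi: HSA 4; GSO 9qp: HSA 8; GSO 13qt: HSA 19.
target_species	target_chrom	order_index	target_region	source_species	source_region	alternatives	flags
GSO	1	1	pt	HSA	4a
GSO	1	2	pi	-	-
GSO	1	3	pp	HSA	10b
GSO	1	4	q	HSA	14a-15a-14b-15b
GSO	2	1	p	HSA	2a
GSO	2	2	q	HSA	6a
GSO	3	1	p	HSA	12a-22a
GSO	3	2	qp	HSA	13b
GSO	3	3	qd	HSA	3a-21
GSO	4	1	p	HSA	9
GSO	4	2	q	HSA	5a:7b:16b
GSO	5	1	p	HSA	10a
GSO	5	2	q	HSA	1a-6b
GSO	6	1	p	HSA	2b
GSO	6	2	q	HSA	11a
GSO	7	1	p	HSA	3b
GSO	7	2	q	HSA	8a
GSO	8	1	p	HSA	13a
GSO	8	2	qp	HSA	8b
GSO	8	3	qi	HSA	4c
GSO	8	4	qt	HSA	11b-22b-12b
GSO	9	1	p	HSA	17
GSO	9	2	qp	HSA	8
GSO	9	3	qi	HSA	4b
GSO	9	4	qt	HSA	19b
GSO	10	1	whole	HSA	18:20
GSO	11	1	whole	HSA	7a
GSO	12	1	p/qp	HSA	5b
GSO	12	2	qt	HSA	1c
GSO	13	1	p/qp	HSA	16a
GSO	13	2	qt	HSA	19a
GSO	14	1	whole	HSA	1b
GSO	15	1	p	-	-		NOR-adjacent
GSO	15	2	q	HSA	15c
GSO	X	1	whole	HSA	X
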