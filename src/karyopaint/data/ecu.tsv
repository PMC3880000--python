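# The 25 chiropteran Evolutionarily Conserved Units (ECUs) as human (HSA)
# segment combinations, located on the MCA karyotype at arm resolution
# (one ECU per MCA chromosome arm; whole = single-row chromosome).
# ecu_id is the HSA segment string stripped of footnote marks.
ecu_id	hsa_segments	mca_chrom	mca_arm
11a	11a	1	p
5a:7b:16b	5a:7b:16b	1	q
2b	2b	2	p
6a	6a	2	q
10a	10a	3	p
3a-21	3a-21	3	q
3b	3b	4	p
8a	8a	4	q
1c	1c	5	p
4a:10b	4a:10b	5	q
17	17	6	p
4b:8:19b	4b:8:19b	6	q
18:20	18:20	7	whole
7a	7a	8	whole
13a:8b-4c	13a:8b-4c	9	whole
14a-15a-14b-15b	14a-15a-14b-15b	10	whole
1a-6b	1a-6b	11	whole
2a	2a	12	whole
12a-22a+13b	12a-22a+13b	13	whole
9	9	14	whole
1b	1b	15	whole
16a:19a	16a:19a	16	whole
11b-22b-12b	11b-22b-12b	17	whole
5b	5b	18	whole
15c	15c	19	whole
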