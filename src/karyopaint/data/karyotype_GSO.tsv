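# Glossophaga soricina (GSO): 15 autosome pairs + X + Y; 2n = 32, FN = 60
# (all autosomes bi-armed). GSO 10 is the metacentric homolog of MCA 7;
# GSO 15 is the bi-armed NOR-bearing smallest pair.
species	chrom	morphology	is_sex
GSO	1	submetacentric	0
GSO	2	submetacentric	0
GSO	3	submetacentric	0
GSO	4	submetacentric	0
GSO	5	submetacentric	0
GSO	6	submetacentric	0
GSO	7	submetacentric	0
GSO	8	submetacentric	0
GSO	9	submetacentric	0
GSO	10	metacentric	0
GSO	11	submetacentric	0
GSO	12	submetacentric	0
GSO	13	submetacentric	0
GSO	14	submetacentric	0
GSO	15	submetacentric	0
GSO	X	submetacentric	1
GSO	Y	acrocentric	1
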