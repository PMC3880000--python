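# Lonchophylla concava (LCO): 13 autosome pairs + X + Y; 2n = 28, FN = 50
# (12 bi-armed + 1 acrocentric autosome; the smallest pair, LCO 13, is the
# FN-constrained acrocentric).
species	chrom	morphology	is_sex
LCO	1	submetacentric	0
LCO	2	submetacentric	0
LCO	3	submetacentric	0
LCO	4	submetacentric	0
LCO	5	submetacentric	0
LCO	6	submetacentric	0
LCO	7	submetacentric	0
LCO	8	submetacentric	0
LCO	9	metacentric	0
LCO	10	submetacentric	0
LCO	11	submetacentric	0
LCO	12	submetacentric	0
LCO	13	acrocentric	0
LCO	X	submetacentric	1
LCO	Y	acrocentric	1
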