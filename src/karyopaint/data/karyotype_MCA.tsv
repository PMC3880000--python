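# Macrotus californicus (MCA): 19 autosome pairs + X + Y; 2n = 40, FN = 60.
# Morphologies of pairs 8, 15, 16 (bi-armed) and 12, 14 (acrocentric) are
# constrained by FN = 60 (11 bi-armed + 8 acrocentric autosomes).
species	chrom	morphology	is_sex
MCA	1	submetacentric	0
MCA	2	submetacentric	0
MCA	3	submetacentric	0
MCA	4	submetacentric	0
MCA	5	submetacentric	0
MCA	6	submetacentric	0
MCA	7	submetacentric	0
MCA	8	submetacentric	0
MCA	9	subtelocentric	0
MCA	10	acrocentric	0
MCA	11	acrocentric	0
MCA	12	acrocentric	0
MCA	13	acrocentric	0
MCA	14	acrocentric	0
MCA	15	metacentric	0
MCA	16	metacentric	0
MCA	17	acrocentric	0
MCA	18	acrocentric	0
MCA	19	acrocentric	0
MCA	X	submetacentric	1
MCA	Y	acrocentric	1
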