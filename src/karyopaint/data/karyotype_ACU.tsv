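# Anoura cultrata (ACU): 14 autosome pairs + X + Y; 2n = 30, FN = 56
# (all autosomes bi-armed). ACU 10 is the subtelocentric homolog of MCA 7;
# ACU 8 and 11 are metacentric homologs of the acrocentric MCA 10 and 11.
species	chrom	morphology	is_sex
ACU	1	submetacentric	0
ACU	2	submetacentric	0
ACU	3	submetacentric	0
ACU	4	subtelocentric	0
ACU	5	submetacentric	0
ACU	6	submetacentric	0
ACU	7	submetacentric	0
ACU	8	metacentric	0
ACU	9	submetacentric	0
ACU	10	subtelocentric	0
ACU	11	metacentric	0
ACU	12	submetacentric	0
ACU	13	submetacentric	0
ACU	14	submetacentric	0
ACU	X	submetacentric	1
ACU	Y	acrocentric	1
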