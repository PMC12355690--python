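coformer	delta
pyrazine	0.38
3-methylpyridine	0.36
theophylline	0.08
imidazole	0.07
2-amino-5-methylbenzoic_acid	0.06
ferulic_acid	0.06
apigenin	0.05
ketoglutaric_acid	0.05
4-aminobenzoic_acid	0.03
EDTA	0.03
ethylparaben	0.02
hesperetin	0.02
propylparaben	0.02
d-pantothenol	0.01
methylparaben	0.01
glutaric_acid	0.01
glycolic_acid	0.01
l-mandelic_acid	0.01
zero_scoring_coformer_1	0.00
zero_scoring_coformer_2	0.00
zero_scoring_coformer_3	0.00
zero_scoring_coformer_4	0.00
zero_scoring_coformer_5	0.00
zero_scoring_coformer_6	0.00
isonicotinamide	-0.13
nicotinamide	-0.14
lowest_scoring_coformer	-0.24
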