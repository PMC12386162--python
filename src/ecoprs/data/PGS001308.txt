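#format_version=2.0
#pgs_id=PGS001308
#trait_reported=Sjogren's syndrome
# Variant weights of the published seven-variant score. Effect alleles follow
# the 1000 Genomes strand-corrected annotation; other_allele is not recorded
# in the published weight list and is omitted. The rsID-less chr6 variant's
# effect allele is a placeholder (the variant is excluded at harmonization).
rsID	chr_name	chr_position	effect_allele	effect_weight
rs2394517	6		T	0.0953
rs3131044	6		C	0.0791
rs1264319	6		T	0.1132
rs3131787	6		C	0.0845
chr6:31474000	6	31474000	A	0.0956
rs185819	6		C	0.0823
rs2004640	7		T	0.0789
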