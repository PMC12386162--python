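# Effect-allele frequencies, 1000 Genomes Phase 3 European populations.
# Column headers carry the allele each frequency refers to (rsid:ALLELE).
population	rs2394517:T	rs3131044:C	rs1264319:T	rs3131787:C	rs185819:C	rs2004640:T
CEU	0.586	0.141	0.192	0.182	0.53	0.47
TSI	0.575	0.07	0.159	0.178	0.603	0.397
FIN	0.682	0.071	0.121	0.121	0.525	0.475
GBR	0.577	0.093	0.22	0.192	0.495	0.505
IBS	0.495	0.093	0.126	0.107	0.589	0.411
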