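# Genome characteristics of the six compared Polynucleobacter taxa
# (assembly accessions in the public nucleotide archives).
strain	lifestyle	genome_size_mbp	gc_molpct	accession
MWH-HuW1	free-living	2.32	45.5	LOJJ00000000
MWH-JaK3	free-living	2.05	45.4	LOJI00000000
QLW-P1DMWA-1	free-living	2.16	44.8	CP000655
MWH-MoK4	free-living	2.03	45.2	CP007501
beta-proteobacterium-CB	free-living	2.05	46.1	CP004348
STIR1	endosymbiont	1.56	45.6	CP001010
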