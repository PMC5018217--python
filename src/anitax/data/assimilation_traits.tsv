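# Carbon-source assimilation phenotypes of the four free-living Polynucleobacter
# type strains (DSM 18221, DSM 21493, DSM 21492, DSM 21495); + assimilated,
# - not assimilated.
Characteristic	QLW-P1DMWA-1	MWH-JaK3	MWH-HuW1	MWH-MoK4
Propionic acid	+	+	+	-
Oxaloacetic acid	-	+	+	+
L-Glutamate	+	-	+	-
L-Aspartate	+	-	-	-
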