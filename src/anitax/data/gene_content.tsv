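# Annotated gene-content differences between the four free-living
# Polynucleobacter type strains (presence/absence calls from genome
# annotation; consumed here as a fixed trait table).
Genes putatively encoding	QLW-P1DMWA-1	MWH-JaK3	MWH-HuW1	MWH-MoK4
ABC-type Fe3+ transport system	-	+	+	+
feoAB genes (uptake of Fe2+)	+	+	+	-
ABC-type nitrate/nitrite/cyanate transporter	+	+	-	-
Nitrate reductase (assimilatory)	+	+	-	-
Nitrite reductase (assimilatory)	+	+	-	-
Cyanate lyase	+	+	-	-
Urease and ABC-type urease transporter	+	-	-	-
Cytochrome bd-I terminal oxidase (CydAB)	+	-	+	-
Fumarate reductase	-	+	-	+
Carbon monoxide dehydrogenase	-	+	-	+
Acetate permease actP	+	-	-	-
Photosynthesis gene cluster	-	-	-	+
Flagella genes	-	-	-	+
Catalase	2 genes	1 gene	-	-
Cellulose synthase operon protein C	+	-	-	-
Cellulose synthase catalytic subunit	+	-	-	-
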