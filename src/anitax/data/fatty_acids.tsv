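# Cellular fatty acid composition (% of total fatty acids) of the four
# free-living Polynucleobacter type strains; - means not detected.
Fatty acid	QLW-P1DMWA-1	MWH-JaK3	MWH-HuW1	MWH-MoK4
C12:0	3.4	3.7	5.5	3.8
C14:0	0.9	1.2	0.3	0.3
C15:0	0.3	-	0.3	-
C16:0	22.2	15.5	29.6	15.9
C17:0	-	-	0.5	-
C18:0	1.2	0.5	2.4	0.5
C20:0	1.1	-	-	-
C14:1w5c	-	0.6	0.2	-
C15:1w6c	-	-	0.6	-
C16:1w5c	0.9	0.4	-	0.4
C16:1w7c	41.3	35.6	45.0	38.6
C18:1w9c	-	-	0.4	0.3
C18:1w7c	12.9	20.4	1.1	19.8
11-Methyl C18:1w7c	3.1	8.1	1.1	4.2
C12:0 2-OH	2.5	2.2	1.3	1.3
C16:0 2-OH	-	-	-	1.8
Summed feature 1	0.4	0.5	1.0	-
Summed feature 2	9.6	9.2	9.9	11.9
Summed feature 7	0.4	2.0	0.3	-
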