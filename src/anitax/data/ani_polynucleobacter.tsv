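# Pairwise ANI (%) of the five genome-sequenced Polynucleobacter taxa
# (upper triangle as published).
	STIR1	QLW-P1DMWA-1	MWH-MoK4	MWH-JaK3	MWH-HuW1
STIR1		78.0	76.1	84.1	76.3
QLW-P1DMWA-1			75.7	78.3	75.7
MWH-MoK4				76.4	78.4
MWH-JaK3					76.7
MWH-HuW1					
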