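# Diagnostic oligonucleotide signatures for the PnecC species complex.
name	sequence	expected_region
PnecC-16S-445	GAGCCGGTGTTTCTTCCC	16S rRNA, E. coli positions 445-463
ITS-diagnostic	ACTAAGCGATCTAATGATTGTTTA	16S-23S ITS
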