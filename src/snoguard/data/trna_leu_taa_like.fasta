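>tRNA-Leu-TAA-synthetic synthetic reconstruction of a mature tRNA-Leu(TAA); not a database sequence
GGTAGCGTGGCCGAGCGGTCTAAGGCGCTGGATTAAGGCTCCAGTCTCTTCGGAGGCGTG
GAACCCCATCGCTCCTGGCCGTA
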