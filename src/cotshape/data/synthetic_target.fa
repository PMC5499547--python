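>synthetic_fluoride_riboswitch_target synthetic 45-nt promoter + 120-nt target (nontemplate strand)
CGTGTGAGTGAATGCGCCTCGTGCAGGACCCATGCGGAGAAAACCGAGGTTCCGGAAATC
GATATCGTATGAGCGCTACAGGTTGGCTAGATGCAGGTTAAGAAATTCCTCGATGCCGAC
ACCTTAAAATCCGATCTGGCATTCATATTCAGTTACGCGGTCCTT
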