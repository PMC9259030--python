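>synthetic_amplicon offset=3000 positions=3001-3400
ACAACGGCACTCCACTCTCTTGTGCCGCTTTCAATGTTGCCCTGGGTAGAAGCACGTGTCTAAGTAATCG
AAAACATCGTTGGCTAAAGTACCCGGTCTTTTATAGCATAAACGCGAAGGAAGGCCCACTGTCGGCTTGA
TGGGGGATCGGCTTTGTTGTCTTCCCTCACTACCGCTATCATGATTGCCCGGGTGCAGTTTGTTAATCGT
ACGTGCTAGTGACGGTAAGTTCGAACTAGAAGAGCTCCTTTTCCATTATGTCATTGTCTTTGCCCCCGGA
GTTCCATCGGCTGTTTTGGGAAGCCGTAGATTTTTCACGATAGATAAATTAAGTTCCCGAAAAATCTTAG
AGACATACTGGCCCGTTGAGCAAAAGTCTATATTATTATGGGGGGTAGCA
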