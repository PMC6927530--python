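>sog_Distal 658-bp enhancer, ~12 kb upstream of short gastrulation
GCGGCCGCGACAGATTCCCGGGTTTCAGCGGAACAGGTAGGCTGGTCGATCGGAAATTCC
CACCATACACATGTGGCTATAATGCCAACGGCATCGAGGTGCGAAAACAGATGCAGCCTC
ATAAAAGGGGCGCAGATAAGGTCGCGGTTGCGTGGGAAAAGCCCATCCGACCAGGACCAG
GACGAAGCAGTGCGGTTGGCGCATCATTGCCGCCATATCTGCTATTCCTACCTGCGTGGC
CATGGCGATATCCTTGTGCAAGGATAAGGAGCGGGGATCATAAAACGCTGTCGCTTTTGT
TTATGCTGCTTATTTAAATTGGCTTCTTGGCGGGCGTTGCAACCTGGTGCTAGTCCCAAT
CCCAATCCCAATTCCAATCCGTATACCCGTATATCCAATGCATTCTACCTGTCCTGGGAA
TTTCCGATTTGGCCGCACCCATATGGCCACGGATGCGTGAGAGTGCTCTCCGTGCGATTC
TAGATCATCGTGGGTATTCGCAGACAATCGGGTTATTGTGCCGCATTCGATGTTGGCTCT
TTGGTTTTCGGAAACTCTGACCAGGTTTTCGGTTTTCGGTTTTTGATTTTGGGTTTTTCC
GGCCGCATCGTGCGTCATCTGGTGGCACAGGACGCACTTGCCCCTGTCAGTTAGATCT
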