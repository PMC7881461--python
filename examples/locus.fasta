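>locus
TCTGATTTACCTGTCAGATGTCTTTACAAGGTCCCAACAGCTGCTTCCGAAATGGTCGAAGCGTGGGCAC
ACTAACCGGTGCTAAAGCAGAGCCCGCAATTGCTTGCCATCACGATTGCGGGACACCAAGATGCGATCTA
CCTGCCCGCATTAGAGCGGTATAAGCTTCTCGCTAACTTGTTGCTGCAGCTAATAAGTACTTGAAAAGAG
GGATGGAATCCCGTCTAGGAACTGTTCTAATTAGGTGCCCGTCAAGTAAGATCATACAAAAAAGGCCGTT
AAAAGCACGATATATTTTTGTAGGTCCGCACCACCCCGCTTCCGTGTGGCGAGTAGAGATATTGTTTCGA
GAGGCGTTCGTAAAGCTGCTTCCCAATCCGGTTCCTGTATGAGGACTCCCCTTATTCTATGGATAAATAT
GAAAGTATATTTGTAAAGGGTAGACGTGAGATGAAATCTGGATCGGGTAGCCAACCCGGCCAGCACCAGG
GGGCTGCGCGGTTGGTCTCAATACCACGATTCAGACTTTCGGCGAAGAATTGTTACCATCCAATAACCGC
AATGGGTACGCTCTTGTGTCCGACTGACAATCCGACGGTGCTTGTTTAGCGGTTCGGCAATCTCTCTAGT
TTACAAGGTTGTAAGTAGGACTGATCTCGCCTAACGTTCCAGTGGCTCACAAACGCCTTGCTACTGGGGC
ACATCGTTCCTGTTTAGAGTGCATAAAACGCAACAGACCCAATAGCCCTTCCACGACTACGAAATAAAAG
AGGTATGATTCTCGTCTCTGACCAACAAGGGCTGAAGAGTAATGATTGGCAGCGTAGATCGGCGGGTTCG
ATGCATCGATAATTACGTCGGGTGATTTAAGATCGTCCGGCGTCACCAAGCTAATTCAAGCCACTGCACC
TTTTTTAACGATGGACATGGCCCTTATATACTACCAGTTCGAAATTTGCGGCAATCTAGACAATCGCCGA
TTGCATCACTGTTATCGATCACAAGCTCGCGGCTCAGTACTGTGGCTCGCGGGTCGCCCAAGGGACATTA
GACACGTAGGTGCGCTCGACTGCTTCGCGCATTTTGTTCCAGCCGCATTAACTTATACTAACGTTAATCT
GATACGGGGTTGAGTCCCAGCTTTCCGTCTATAAGAAACTAGTAATTGTACGCTGTCCAATAAAATCTAG
CCTTTAAGCGGGTGAAGCCCTTGCCGCGGAAATGATCCTAAGAGAAACAATCCACCGATTAAAGATTTGT
ACCTGTATCCTCCGACAATGCCCGTTCCCGCGGCCCAAGCAGTCTTGGATCTGAAGGAGTCCATCTCGCA
TCGTTTAGTCATCGTGCCCATTCCTAGCGAGCGACGAAACATCTTAGTGCCAGTTAGCTATTAATAGTGC
CATCACTATGTTTTATGGTTGCCCCCAATCTGAAATAGTTAAAAAGTGGATGTTCAACTCTGACGGCAGA
TAACGGCTCCCAGAGATCTCATGTCGTGCGGTCCTGGCAGAAGGTCATAACGTTGACCACCAGGACTGTC
TACACCATCCACCCATTCGTTGTTTCAACCCGGTAATTTTTCCCGTCGCAAATCTGAATCTAGTACTCCC
CTTCTAAGTAAGTACGCAACCTGGTCCTAGTACAACCTTTCCCATCATCAAGTATTTAATCGTATTGCTG
GTGCAAGGGCTTAGGGATTGTTCGCTACTCTCTTCTCGGTAAGGCACTACTAGCTGTAGTAAATGGGGCC
GATTCGATTTCAAAAATAATGTGTGGGCCCATCAATCGTATCAGTCGCGGGGAGGGACCAACGATGTCCG
TCGGGAGCTCCTCAAAACTGAGATAGCGCTATGTTTACCCGTTGGTTAGTCCTTTTCCGGGGCGCCAATC
ATGACAGCAAGATAGCCATTAATGAAGGGTCCCCAACGACGGTTGACGAAACCATTATATTATTTTGATG
GCGAGAGTCGCTGCAACTGATCTAGTCGTAAGCACTCCTG
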