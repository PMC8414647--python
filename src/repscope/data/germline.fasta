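>IGHV1-2*01
GGTCTGTCCAGTCGCGATCTACCGGCTATGCAACGGTCCCCATATATGTTGCAGTCTCTCTGCCCCCCCGGTCACAGCAGTAGGCCGTTCATAGTGGTTAATCTCTGTGCGAGA
>IGHV3-7*01
CGTCTTCACGGCTTATCGTGGCGCGAGACAGCGCCCTGGTGCCCCTTACTCCTACTGTCGCAATTTGTTGACGGTGTAGAGAAAGCCATCGGCGACGGCCAATCATGTGCGAGA
>IGHV4-34*01
GATGTAATCACAAACCATTCGGAGTGGCTTTGTTTTTCTAAGGGGCAGCGATTACCTAAGTATGACCTTTTTGGTGCCATATTGATCGTTCATACTGTAGGATTGTGTGCGAGA
>IGHD2-2*01
TGGTGTTAACCTTACT
>IGHD3-10*01
GCATACGTGTACGCCC
>IGHJ4*02
AATCGGGACACTTGGGGCCAAGGGACCACGGTC
>IGHJ6*02
GCTTAAAAGCCATGGGGCCAAGGGACCACGGTC
>IGHM*01
CTCGCGCACGGTACTAGTTGTATGGTTATT
>IGHG1*01
TCGATACGACATCTCTAACGAGGACCTCCA
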