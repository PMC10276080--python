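>IGHV1-2*01
AGAGCCTTTATCCTCGTTTACGGAACATGTGGCCACTCTCGCTACCTTCCACAATCTCCTGCCTCCTGCTATAACACAATTATCCTACCCAAAAAGGCGCTTGCGGTAACGACCCGGCGCTGGACAGGAGAAAATAGTACACATCAGGCCGAGATTGCCCCGACACTAGTCACCCAAACGGAGATAATT......AGGGACCGCCGCGGTGACTATTCACTGGCGTTGGAACGAGTTCCTATTTGCAGCCCAACCCACAACGCAGTTTATATAATACTGTTAGTTATGCCCCTAAGGTCTCTGGGTTTTTGT
>IGHV2-70*01
AGAACCTTTATTCGCGAGTACGGAACATGTGGCCAATCTCGTTACCTTCCACAATCTCCATCCTCCTGCTATAACAGAATTGTCATACCGAAAAACGCGCTT............CGGCGCTGGACCGGAGAAAGTAGATCACTTCAAGCCGGCATTGCCCTGACAGGAGGAACCCTAGTGGAGTTC.........AGCGACCGGCGCAGTGACCCATTACTGGCGTTTGATCGAGTTCATAGTTCCAGCCCAAAGCAGAACGCAGTTTATACACTACTGTTAGTTATGCCCGTAAGGTTTCCGCGTTTTTGT
>IGHV3-23*01
AGAACCTTGATCAACGTGTACGGAACATGGGACCAATCTCGTTACCTACTACAATCTCCTGCCTCCTGCTTTAACAGAATTGTCATACGGACAATGGCCCTC............CGGCGCTGGATCGGAGAACATAGGACTCATCAAGCCGGGATTCCCCTGACAGCAGACTCCCAAATGGAGTTC.........AGCGACCGGCGCAGTGACCCATCACTGACGTTTGGACGAGCTCATAGTTGCATCCGAACGAAGAACGCTGTTTGTACAATACTGTTAGTTATGCCCCTAAGGTTTCTGGGTTTCTGT
>IGHV4-30-2*01
AGAACCTTTATCAACGTGTACAACAAATGGGGCCAATCTCCTCACCCTCCACAATCTACTGCCTCCTGCTACAACAGATTTGTGATAACGAAAAAGGCGCTC............CGGCGCTGGACCGGAGAGAATCGAAGACATCAAGCCGGGATTGCCCTGACACCTGTATCCCAAATAGAGGTCATT......AGGGAACGCCGCAGTGACCCGTCACTGGCCTTTGAACGACTTCATAGTTGCAGCCCAACGCAAAACGCAGTTTATACAATCCTGTTAGTTATGCCCCTAAGGTTTCTCGGTTTTTGT
>IGHV4-31*01
AGAACCTTTATCCACGTGTCCGTAACATGTGGCCAACCTCGTGGCCGTCCACAATCTCGCGACTCCTGCTATGACAGAATTGTCGTACCGGACAAGGCGCTCGCGAAC......CGGCGCTGGACCGGAGAAAATAGAACACATCTAGTCGGGATTGCCCTGACACCAAGCGCCCAAATGGACCGTATT......AGCGACGAGCGAAGTGACCCATCACTGGCGTTTGAACGAGTACATGGTTGCAGCCCAACGCACAACGCAGTTTATACAATACTGTTAGTTATGCCCCTAATGCTACTGGGTTTCTGT
>IGHV4-34*01
AGAACCTTTATGCACGTGTACGGAACATGTGGGCAATCTCGTTACCTTCCGCAATCTCCTGTCTCCTGCTATAACAGAATTGTAATACCGAAAAAGGCGCGCCTGGTCCCGATGCGGCTTTGGACCGCAGACAATATAACACATCAAGCCCGGGTCTCACTGACACCAGGCACCCACATGGAGTCCATTGTAGGAAGCTACCGGCGCAGTCACCCAGCACTGGCGTTTGAACGAGTTCATAGTTGCACCCCAACGCACAACGCAGTTTATACAATACTGTTAGATATGCCCCTAGGGTTTCTCGGTTTTTGT
>IGHV5-51*01
AGAACCTTTATCCACGTGTACGTAACAGGTGGCCAATCTCGTTACTTTCAACAATCTCGTACCTCTTGCTATACTAGATTTATAATACCCAAAAAAGCGCTCGCGATCAAGGTCCGGCGCTGGACCGGAGGAAATAGAACACATCAACTCGGGATTGCCCTGACAACAGCCACCCAAATGGAGTTC.........AGCGACCGGAGCAGTGACCCATCACTGGCGTTTGAACGAGTTCATAGTTGCAGACCAACGCATGACGCAGTATATACAATACTGTTAGTTATGCCCCTAGGGTTTCAGGGTTTTTGT
>IGHV6-1*01
AGAACCTATCTCCACGTGTACGGGACATGTGGCCAATCGCGTTACCTTCCACAATCTCCTGCCTCCTGCTATACCAGAATTGTCCTACCGAAAAAGGCGCTG............CGGCGCTGGATTGTAGAAAATAGAACACATCACGCCGGAAGTGCCCTGACAACAGGGACCCAACAGGTGTTCATT......AGCAACCGGCGCAGTTACCCATCACTGGCGTTTGAAGTTGTTCATAGTTGCAGCCCAACTCACAGCACAGTTTACACAATACTGTTAGGTATGCTCCTAAGGTTTCTGGGTTTTTGT
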