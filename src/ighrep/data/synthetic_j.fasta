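>IGHJ3*01
GCCTTTGACATATGGGGGCAAGGGACTATGGTCACCGTTAGCTCA
>IGHJ4*01
TACTTCGACTACTGGGGGCAGGGGACGTTAGTAACGGTTTCTAGT
>IGHJ5*01
AACTGGTTTGATAGCTGGGGCCGCGGTACACTCGTAACCGTATCAAGC
>IGHJ6*01
TACTATGGCATGGACGTTTGGGGAAAGGGGACAACCGTAACTGTCAGCTCA
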