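name	sequence
BbsI_apc1_for	ATAAGAAGACCTTGCAGGGCATCGCCGAGCTCAGTCGTTTCAGAGCTATGCTGGAAAC
SapI_apc2_for	ATAAGCTCTTCCTGCAGGAGAGACGATCCGCTCAGAGTTTCAGAGCTATGCTGGAAAC
BbsI_cic_for	ATAAGAAGACCTTGCAGGCTTGCCCGGGGAGCTTAGGTTTCAGAGCTATGCTGGAAAC
SapI_p53_for	ATAAGCTCTTCCTGCAGGCTATTACGTGCCCCAATAGTTTCAGAGCTATGCTGGAAAC
BbsI_Med_for	ATAAGAAGACCTTGCAGGTGAAGGACGAATACTCAGGTTTCAGAGCTATGCTGGAAAC
final_rev_Pten_BbsI	ATAAGAAGACCCAAACGACGGTTTCTGAATAGGCCCTGCACCAGCCGGGAATCGAACC
universal_rev_2xSapI_BbsI	ATAAGAAGACCCAAACTGAAGAGCTGAACGGCTCTTCTGCACCAGCCGGGAATCGAACC
universal_rev_2xBbsI_SapI	ATAAGCTCTTCAAACTGGTCTTCTGAAGGGAAGACTATGCACCAGCCGGGAATCGAACC
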