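gene	protospacer	reported_offtargets
apc1	GGGCATCGCCGAGCTCAGTC	3
apc2	GGAGAGACGATCCGCTCAGA	5
cic	GGCTTGCCCGGGGAGCTTAG	4
p53	GGCTATTACGTGCCCCAATA	5
Med	GGTGAAGGACGAATACTCAG	1
Pten	GACGGTTTCTGAATAGGCCC	4
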