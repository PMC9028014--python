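gene	role
CG3902	acyl-CoA dehydrogenase (fatty acid beta-oxidation)
CG4860	short-chain acyl-CoA dehydrogenase (fatty acid beta-oxidation)
CG5599	dihydrolipoamide transacylase, branched-chain/fatty acid degradation
CG9547	glutaryl-CoA dehydrogenase family (fatty acid beta-oxidation)
CG31075	aldehyde dehydrogenase (ALDH1A orthologue; KEGG fatty acid metabolism, not core beta-oxidation)
Mtpalpha	mitochondrial trifunctional protein alpha subunit
whd	carnitine O-palmitoyltransferase I (CPT1, rate-limiting FAO entry step)
yip2	3-ketoacyl-CoA thiolase (final beta-oxidation step)
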