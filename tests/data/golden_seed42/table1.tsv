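phenotype	n_mqtl_cpg_sites	n_mqtl_genes	n_eqtl_genes	n_pqtl_genes	integrated_genes	strong_coloc
synthetic_pain	16	4	4	3	GENE01,GENE02,GENE03	GENE01
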