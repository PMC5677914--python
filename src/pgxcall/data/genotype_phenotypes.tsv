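# Single-locus phenotype translation for genes typed through one tag variant.
# phenotype_gene names the gene reported on (the two HLA tag SNPs report on
# HLA-A and HLA-B separately even though the panel groups them under "HLA").
# Columns ref_hom / het / alt_hom give the phenotype class for each genotype.
panel_gene	phenotype_gene	rsid	ref_hom	het	alt_hom	basis
SLCO1B1	SLCO1B1	rs4149056	normal_function	decreased_function	decreased_function	CPIC
VKORC1	VKORC1	rs9923231	normal_function	decreased_function	decreased_function	CPIC
IFNL3	IFNL3	rs12979860	normal_function	decreased_function	decreased_function	CPIC
HLA	HLA-A	rs1061235	non_carrier	carrier	carrier	CPIC
HLA	HLA-B	rs2395029	non_carrier	carrier	carrier	CPIC
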