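subtype	category
Phosphoserine	Phosphorylation
Phosphothreonine	Phosphorylation
Phosphotyrosine	Phosphorylation
N-acetylalanine	Acetylation
N-acetylmethionine	Acetylation
N6-acetyllysine	Acetylation
N-acetylation	Acetylation
O-GalNAc	O-linked glycosylation
O-GlcNAc	O-linked glycosylation
N-linked (GlcNAc...) asparagine	N-linked glycosylation
C-linked (Man) tryptophan	C-linked glycosylation
Methylarginine	Methylation
Omega-N-methylarginine	Methylation
N6-methyllysine	Methylation
N6,N6-dimethyllysine	Methylation
N6,N6,N6-trimethyllysine	Methylation
N6-crotonyllysine	Crotonylation
N6-succinyllysine	Other modified residue
4-carboxyglutamate	Gamma-carboxyglutamic acid
4-hydroxyproline	Hydroxylation
5-hydroxylysine	Hydroxylation
N-myristoyl glycine	Myristation
S-palmitoyl cysteine	Palmitoylation
S-geranylgeranyl cysteine	Prenylation
S-farnesyl cysteine	Prenylation
S-nitrosocysteine	S-nitrosylation
Sulfotyrosine	Sulfation
Glycyl lysine isopeptide (Lys-Gly) (interchain with G-Cter in SUMO)	Sumoylation
Glycyl lysine isopeptide (Lys-Gly) (interchain with G-Cter in ubiquitin)	Ubiquitylation
Ubiquitination	Ubiquitylation
Sumoylation	Sumoylation
Amidation	Amidation
Active site	Active site
DNA binding site	Binding site
ATP binding site	Binding site
Ca2+ binding site	Binding site
Zn binding site	Binding site
GEF interaction site	Binding site
Substrate binding site	Binding site
Dimer interface	Binding site
Cytokine receptor motif	Binding site
Lipid moiety-binding region	Other lipid modification
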