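# oncopanel knowledge-base snapshot, version 2023-01
# Breast-cancer actionability entries (OncoKB-style), curated statically for
# reproducibility. Matching is case-insensitive on genes and normalization-
# invariant on protein changes. Replace with your own snapshot as needed.
alteration_kind	gene	protein_change	therapy	evidence_note
variant_hotspot	PIK3CA	p.Asn345Lys	PI3Kalpha inhibitor (alpelisib) + ER antagonist (fulvestrant)	HR-positive HER2-negative BC after endocrine therapy
variant_hotspot	PIK3CA	p.Glu545Lys	PI3Kalpha inhibitor (alpelisib) + ER antagonist (fulvestrant)	HR-positive HER2-negative BC after endocrine therapy
variant_hotspot	PIK3CA	p.His1047Arg	PI3Kalpha inhibitor (alpelisib) + ER antagonist (fulvestrant)	HR-positive HER2-negative BC after endocrine therapy
variant_hotspot	PIK3CA	p.His1047Leu	PI3Kalpha inhibitor (alpelisib) + ER antagonist (fulvestrant)	HR-positive HER2-negative BC after endocrine therapy
variant_hotspot	PIK3CA	p.Gly1049Arg	PI3Kalpha inhibitor (alpelisib) + ER antagonist (fulvestrant)	HR-positive HER2-negative BC after endocrine therapy
germline_gene	BRCA1	NA	PARP inhibitor	pathogenic germline variant, with or without biallelic loss
germline_gene	BRCA2	NA	PARP inhibitor	pathogenic germline variant, with or without biallelic loss
germline_gene	PALB2	NA	PARP inhibitor	pathogenic germline variant, with or without biallelic loss
tmb_high	NA	NA	immune checkpoint inhibitor	TMB >= 10 mut/Mb
msi_high	NA	NA	immune checkpoint inhibitor	MSI-high phenotype
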