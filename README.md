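# oncopanel

Post-variant-calling tumor profiling for targeted cancer gene panels, built
around the analysis workflow used for comprehensive panels such as a 523-gene
/ 1.94 Mb hybrid-capture assay. It is aimed at molecular-pathology and
translational-research groups who already have upstream caller outputs
(annotated somatic VCFs, gene-level copy-number fold-changes, homopolymer
read-length histograms) from tumor-only FFPE sequencing — for example of rare
cohorts like male breast cancer — and need reproducible downstream
classification and reporting.

## What it computes

For each sample:

- **Driver triage** — a variant is a pathogenic (driver) somatic candidate iff
  it is caller-PASS, non-synonymous exonic or splice-site, has allele fraction
  VAF ∈ [0.05, 0.90], total depth ≥ 40, gnomAD popmax AF < 0.01, and is
  flagged somatic in the Cancer Gene Census and pathogenic in COSMIC. Every
  failed condition is recorded in an audit trail.
- **LOH** — at each known germline pathogenic variant (e.g. *BRCA1/2*,
  *PALB2*), loss of the wild-type allele is called when the tumor VAF > 0.50.
- **Copy number** — gene fold-change FC classifies as gain if FC ≥ 1.5
  (≈ 3 copies), loss if FC ≤ 0.5 (1 copy), with copies = round(2·FC).
- **TMB** — eligible coding variants (including synonymous, excluding database
  hotspots and germline) per megabase of target; TMB ≥ 10 mut/Mb is high.
- **MSI** — each homopolymer locus with ≥ 60 reads is assessed; a locus is
  unstable when its off-reference read fraction exceeds the stutter baseline
  by > 0.20 (a Jensen–Shannon variant is available). MSI% = 100 ·
  unstable/assessed; ≥ 10% is MSI-high, 0 unstable is stable.
- **Actionability** — drivers, germline variants and biomarker strata are
  matched against a bundled, versioned knowledge-base snapshot (PIK3CA
  hotspots → PI3Kα inhibitor + ER antagonist; BRCA1/2, PALB2 germline → PARP
  inhibitor, with or without biallelic loss; TMB-high / MSI-high → immune
  checkpoint inhibitor).

Cohort-level: per-gene mutation and amplification frequencies, biomarker
medians/ranges, actionable fraction, germline/LOH summary and an
oncoprint-style sample × gene matrix.

A synthetic-data module generates seeded FFPE-like cohorts with full ground
truth (hotspot drivers at cellularity-scaled VAFs, low-VAF deamination
artifacts, germline variants with optional allelic imbalance, amplifications,
stutter histograms), plus a deterministic 15-sample fixture cohort encoding a
published male-breast-cancer profiling table.

## Worked example

```python
from oncopanel import (ThresholdConfig, build_sample_profile, default_kb,
                       emit_paper_fixture, summarize_cohort)

cfg, kb = ThresholdConfig(), default_kb()
cohort = emit_paper_fixture()          # 15-sample fixture, no downloads
metas = {m.sample_id: m for m in cohort.metas}
profiles = [
    build_sample_profile(sid, cohort.variants[sid], cohort.cnv_calls[sid],
                         cohort.msi_observations[sid], metas[sid],
                         cohort.panel, cfg, kb)
    for sid in cohort.sample_ids
]
s = summarize_cohort(profiles, cohort.metas)
print(s.n_actionable, s.percent_actionable)      # 11 73.3
print(s.gene_variant_freq["PIK3CA"])             # {'n_samples_mutated': 6, 'percent': 40.0}
print(s.cnv_gene_freq["MYC"])                    # {'n_gain': 8, 'n_loss': 0, 'percent': 53.3, 'median_gain_fc': 1.9}
print(s.tmb_summary["n_high"], s.msi_summary["n_high"])  # 2 2
print(s.germline_summary)                        # {'n_carriers': 4, 'percent_carriers': 26.7, 'n_with_loh': 2}
```

11 of 15 samples (73.3%) carry at least one clinically actionable alteration;
PIK3CA is the most frequently mutated gene (6 samples, 40.0%); MYC is the most
frequently amplified gene (8 samples, median fold-change 1.9); two samples are
TMB-high, two MSI-high; two of the four germline carriers show LOH.

The same pipeline is scriptable from the shell:

```sh
oncopanel simulate --paper-fixture --out fixture/
oncopanel triage --vcf fixture/MBC03.vcf --sample-id MBC03 --out drivers.tsv --audit audit.tsv
oncopanel biomarkers --vcf fixture/MBC03.vcf --sample-id MBC03 \
    --cnv fixture/cnv.tsv --msi fixture/msi.tsv --meta fixture/meta.tsv --out MBC03.json
oncopanel report --profiles profiles/ --meta fixture/meta.tsv --out report/
```

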