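# Methods

## Scope and data model

oncopanel starts where the upstream callers stop. Read alignment, somatic
variant calling, copy-number calling and functional annotation are out of
scope; their outputs are the pipeline's inputs. An annotated call set is a
VCF 4.2 whose INFO fields follow a fixed tag convention (`GENE`, `CSQ`,
`VAF`, `DP`, `PMAF`, `CGC`, `COSM`, `HGVSC`, `HGVSP`, `ORIGIN`;
per-allele fields are Number=A, and multi-allelic records are decomposed to
one in-memory variant per ALT). Any annotation pipeline can be adapted by
mapping its output onto these tags. Missing optional annotations are kept as
explicit missing values; `CGC`/`COSM` behave as flags, so absence means
false. VCF coordinates are 1-based inclusive, panel BED intervals 0-based
half-open; conversions are centralized in `io_model`.

The modelled assay targets 1.94 Mb across 523 cancer genes, reports
fold-changes for a 59-gene subset and interrogates 125 homopolymer
microsatellite loci. These are defaults of `PanelDefinition`, not
constants — smaller or larger panels are configured, not patched.

## Driver triage

A call is nominated as a pathogenic (driver) somatic variant iff all hold:

1. caller FILTER is `PASS`;
2. consequence ∈ {missense, stop_gained, frameshift, inframe_indel,
   splice_site} — i.e. exonic excluding synonymous, or splice-site;
3. `vaf_min` ≤ VAF ≤ `vaf_max` (default closed interval [0.05, 0.90]; the
   ceiling suppresses likely germline calls in tumor-only data);
4. depth ≥ `depth_min` (default 40);
5. population popmax AF strictly < `popmax_af_max` (default 0.01). A missing
   popmax annotation passes by default (`popmax_missing_passes`): recurrent
   somatic hotspots are typically absent from population databases, so
   treating "not observed" as "fails the rarity filter" would discard
   exactly the variants of interest. The behaviour is a config switch.
6. Cancer Gene Census somatic flag and COSMIC pathogenic flag both set.
   Membership is consumed as boolean annotations rather than queried live,
   trading freshness for reproducibility.

The interval bounds are read literally from their stated operators
("between 5.0% and 90.0%" → closed; "≥ 40" inclusive; "< 0.01" strict) and
are all configurable. Every failing condition is recorded — the predicate is
fully evaluated with no short-circuit — so the audit trail is itself
testable, and the triage of a sample is sorted genomically, making the
output independent of input order. Inframe indels are included as
protein-affecting exonic events even though cohorts dominated by missense /
frameshift / stop-gain variants may never exercise the class.

## LOH at germline pathogenic variants

For samples with known germline pathogenic variants (typically *BRCA1*,
*BRCA2*, *PALB2*), the matching tumor call is located by gene symbol
(case-insensitive) plus HGVS: protein changes are normalized to one-letter
codes (p.His1047Arg ≡ p.H1047R, Ter ≡ *) before comparison, falling back to
the coding change. LOH is called when tumor VAF > `loh_vaf` (0.50,
strictly); a germline variant absent from the tumor call set is
NOT_EVALUABLE rather than silently negative. LOH evaluation reads the raw
call set, not the triaged drivers: a germline variant at VAF 0.95 is
precisely the interesting case and must not be lost to the somatic VAF
ceiling. Copy-neutral LOH (balanced at VAF ≈ 0.5) is invisible to this test
by construction.

## Copy number

Fold-changes (1.0 = diploid) are classified: gain iff FC ≥ `cnv_gain_fc`
(1.5), loss iff FC ≤ `cnv_loss_fc` (0.5), neutral otherwise; the two
thresholds are validated to be ordered so the labels partition. Integer
copies are round(2·FC) with half-away-from-zero rounding so the 1.5
threshold maps to three copies. Neutral calls are reported explicitly
rather than omitted. Per-gene summaries take the median fold-change over
gain calls only; medians throughout the package use numpy's
mean-of-central-pair convention for even counts. Purity/ploidy correction
and segment-level modelling are out of scope.

## Tumor mutational burden

TMB = eligible count / panel megabases, exactly. The eligibility rule
follows the convention of large hybrid-capture assays, since vendor
pipelines for this step are generally unpublished: PASS coding variants
including synonymous, with VAF ≥ `vaf_min`, depth ≥ `depth_min`, popmax <
`popmax_af_max`, excluding database hotspots (`cosmic_pathogenic`) and
known germline variants. Each exclusion is individually toggleable
(`tmb_include_synonymous`, `tmb_exclude_hotspots`, `tmb_exclude_germline`),
so the rule set is an explicit, configurable stand-in rather than a claim
about any proprietary method. The denominator defaults to the panel's
1.94 Mb with a per-sample `callable_mb` override, because real per-sample
callable regions differ from the nominal target size. The high/low cut is
TMB ≥ 10 mut/Mb, inclusive at the boundary.

## Microsatellite instability

Per-locus, the observation is a read-count histogram over repeat lengths
plus a baseline profile giving the expected stutter proportions for a
microsatellite-stable template. Loci below `msi_min_coverage` (60 reads)
are excluded from the denominator. The default instability test is
transparent: shift = max(0, observed off-reference fraction − baseline
off-reference proportion); unstable iff shift > `locus_instability_threshold`
(0.20). This threshold is an implementation parameter — vendor per-locus
algorithms are proprietary — and a Jensen–Shannon-distance test against the
baseline is provided behind the same interface (`msi_method: js`) for
sensitivity analysis. Baselines travel with the locus table and are
user-replaceable; no baseline-construction procedure is imposed.

Sample-level: MSI% = 100 · unstable/assessed. A sample with zero unstable
sites is *stable*; ≥ 10% is *high*; otherwise *low*. Zero assessable loci
yields a *not-evaluable* result, never 0%.

## Actionability

The knowledge base is a bundled, versioned TSV snapshot
(`src/oncopanel/data/kb_snapshot.tsv`), validated at load time (kinds,
required fields, duplicates); it is deliberately static — no live database
queries, no credentials — and swappable. Matching: drivers against hotspot
entries by gene + normalized protein change; germline variants against
germline-gene entries regardless of LOH status (biallelic loss is recorded
in the finding's trigger text, not required for the match); TMB-high and
MSI-high against biomarker entries. Findings are ordered variants →
germline → biomarkers. A sample is "actionable" iff its finding list is
non-empty. Evidence-level grading and indication logic are out of scope.

## Cohort report

Gene mutation frequency counts a gene once per sample. Display percentages
are rounded to one decimal, half-up. Percentages over clinical fields use
the non-missing denominator (e.g. a receptor status missing for one of 15
samples is reported over 14). The oncoprint uses a fixed cell vocabulary
{missense, truncating, frameshift, amplification, germline, none} — stop
gains and splice variants map to *truncating*, inframe indels to
*missense* — with multiple alterations per cell sorted and ";"-joined. All
samples appear in the matrix, including alteration-free ones. The JSON
report round-trips to an equal summary object.

## Synthetic cohorts

`simulate_cohort` emulates tumor-only FFPE panel data at the statistical
level the pipeline consumes (no reads, no realistic genome coordinates
beyond stable per-gene anchors):

- **Drivers** are drawn from a hotspot catalogue (the five breast-cancer
  PIK3CA alterations plus recurrent variants in the other panel genes),
  1–5 per sample, at VAF ~ Normal(cellularity/2, 0.03) with cellularity
  uniform on [0.50, 0.90] — the heterozygous-clonal expectation.
- **FFPE artifacts** are deamination-like C>T / G>A substitutions at
  Poisson(3) per sample with VAF uniform on [0.01, 0.05), i.e. below the
  triage VAF floor by construction; raising `artifact_vaf_range` into the
  filter window is the stress mode for contamination studies (note that
  in-window artifacts then also enter the TMB numerator, as they would in
  a real tumor-only assay).
- **Germline variants** (carrier probability 4/15, matching the modelled
  cohort) have VAF uniform on [0.40, 0.50] without LOH and on
  [0.57, 0.85] with LOH (margin 0.07 above the threshold), so implanted LOH
  status is recoverable exactly.
- **Copy number**: each of the 59 eligible genes gains independently with
  probability 0.061 (reproducing ≈ 54 gains over 15 × 59 gene-samples);
  gain FC = 1.5 + Exp(0.7) capped at 6, neutral FC ~ Normal(1, 0.08)
  clipped to [0.7, 1.3]. Losses are not simulated by default (none are
  expected in this tumor type).
- **MSI**: per-locus stutter baselines put 4–12% of reads off-reference
  (¾ one unit short, ¼ one unit long). MSI-high samples (probability 2/15)
  shift 30% of loci by moving 45–65% of reads to 2–3 units short; other
  samples destabilize each locus with probability 0.01. Locus coverage is
  Poisson(150), so a small fraction of loci fall below the 60-read gate.
- **TMB passengers**: Poisson(8) synonymous/missense non-hotspot variants
  per sample, all passing the eligibility filters, so the eligible count is
  recovered exactly and the TMB stratum deterministically.

The seed fully determines the output, including written files
(byte-identical reruns). What the simulator does **not** model: sequencing
error beyond the stutter/artifact processes, subclonal structure, correlated
copy-number segments, panel-wide coverage variation, matched normals.
Passing recovery tests therefore demonstrate the correctness of the
classification logic under the assay's nominal statistical model, not
performance on real FFPE libraries.

`emit_paper_fixture` is deterministic and encodes a published 15-sample
male-breast-cancer profiling table literally: the four germline carriers
with their LOH statuses, the five PIK3CA hotspot alterations across six
samples, 40 somatic drivers (one to five per sample; the enumerated
per-gene sample counts), 54 copy-number gains in 22 genes across 13
samples with the published per-gene medians, two TMB-high samples (24 and
23 eligible variants ⇒ 12.37 and 11.86 mut/Mb on 1.94 Mb), two MSI-high
samples (22/125 = 17.6%; 17/119 = 14.3% with six loci under the coverage
gate), and one sample whose loci all fail the coverage gate (MSI not
evaluable). Quantities the table does not print — tumor VAFs, depths,
locus histograms, passenger identities — are fixture-invented and labelled
as such in the emitted files' comment headers.

## Problem sizes and numerical notes

The test suite exercises the brute-force triage oracle at 500 random
variants and parameter recovery over 50 seeded cohorts of 15 samples
(~7,500 locus assessments per run); the whole suite completes in well under
a minute on one core. pysam stores INFO floats in single precision, so the
VCF reader rounds VAF/popmax to six decimals, which is also the precision
the writer emits; round-trips are exact at that precision. Degenerate
inputs are defined, not crashed on: empty call sets triage to empty, empty
cohorts summarize without division by zero, zero assessable MSI loci give
not-evaluable, and a zero-read histogram has off-reference fraction 0.
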