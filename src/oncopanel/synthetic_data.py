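"""Synthetic FFPE cohorts with known ground truth, plus the study fixture.

Two generators share the io_model formats:

:func:`simulate_cohort`
    Seeded random cohorts with the statistical structure the pipeline
    assumes — hotspot drivers at tumor-cellularity-scaled allele fractions,
    low-VAF deamination-like FFPE artifacts, germline heterozygous variants
    with optional allelic-imbalance shift, gene fold-changes with occasional
    amplifications, and homopolymer read-length histograms with polymerase
    stutter. Every emitted record is labeled in the returned
    :class:`GroundTruth`.

:func:`emit_paper_fixture`
    A deterministic 15-sample male-breast-cancer cohort encoding the
    published per-sample actionability table literally (germline variants
    and their LOH statuses, the five PIK3CA hotspot alterations, TMB/MSI
    strata, receptor statuses), with cohort-level gene and copy-number
    frequencies matching the published counts. Values the source table does
    not print (tumor VAFs, read depths, locus histograms) are
    fixture-invented and marked as such in the files' comment headers.

The synthetic panel mirrors the modelled assay's dimensions: 523 genes,
59 CNV-eligible genes, 1.94 Mb of target, 125 homopolymer loci. Gene
symbols not needed by the fixtures are synthetic ``SYN###`` placeholders.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_model import (
    AnnotatedVariant,
    CnvCall,
    MsiLocusObservation,
    PanelDefinition,
    SampleMeta,
    write_cnv_table,
    write_msi_table,
    write_panel,
    write_sample_meta,
    write_variants,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedCohort",
    "default_panel",
    "simulate_cohort",
    "write_cohort",
    "emit_paper_fixture",
    "PIK3CA_HOTSPOTS",
    "GERMLINE_CATALOGUE",
]

# ---------------------------------------------------------------------------
# loci and catalogues
# ---------------------------------------------------------------------------

#: Invented but stable genomic anchors for the real panel genes used by the
#: fixtures (synthetic coordinates; only internal consistency matters).
GENE_LOCI: dict[str, tuple[str, int]] = {
    "PIK3CA": ("chr3", 178_910_000),
    "ARID1A": ("chr1", 27_023_000),
    "EP300": ("chr22", 41_488_000),
    "SMO": ("chr7", 128_829_000),
    "SMARCA4": ("chr19", 11_096_000),
    "PAX5": ("chr9", 36_833_000),
    "NCOR1": ("chr17", 15_933_000),
    "MAP3K1": ("chr5", 56_111_000),
    "GATA3": ("chr10", 8_096_000),
    "CREBBP": ("chr16", 3_775_000),
    "TRAF7": ("chr16", 2_205_000),
    "TP53": ("chr17", 7_571_000),
    "PIK3R1": ("chr5", 67_511_000),
    "PDGFRA": ("chr4", 55_095_000),
    "NOTCH2": ("chr1", 120_454_000),
    "NOTCH1": ("chr9", 139_388_000),
    "FOXL2": ("chr3", 138_663_000),
    "CIC": ("chr19", 42_788_000),
    "BRAF": ("chr7", 140_419_000),
    "AXIN1": ("chr16", 337_000),
    "ASXL1": ("chr20", 30_946_000),
    "ARID2": ("chr12", 46_123_000),
    "ABL1": ("chr9", 133_589_000),
    "BRCA1": ("chr17", 41_196_000),
    "BRCA2": ("chr13", 32_889_000),
    "PALB2": ("chr16", 23_614_000),
    "MYC": ("chr8", 128_748_000),
    "CCND1": ("chr11", 69_455_000),
    "FGF19": ("chr11", 69_513_000),
    "FGF3": ("chr11", 69_624_000),
    "FGF4": ("chr11", 69_587_000),
    "CDK4": ("chr12", 58_141_000),
    "MDM2": ("chr12", 69_201_000),
    "ERBB2": ("chr17", 37_844_000),
    "FGFR1": ("chr8", 38_268_000),
    "ZNF703": ("chr8", 37_553_000),
    "CCNE1": ("chr19", 30_302_000),
    "AKT2": ("chr19", 40_736_000),
    "EGFR": ("chr7", 55_086_000),
    "AURKA": ("chr20", 54_944_000),
    "GNAS": ("chr20", 57_414_000),
    "RPS6KB1": ("chr17", 57_970_000),
    "MCL1": ("chr1", 150_547_000),
    "IGF1R": ("chr15", 99_192_000),
    "KRAS": ("chr12", 25_358_000),
    "MET": ("chr7", 116_312_000),
    "CDK6": ("chr7", 92_234_000),
    "BRD4": ("chr19", 15_349_000),
}

#: The five breast-cancer-specific PIK3CA hotspot alterations:
#: (chrom, pos, ref, alt, hgvs_c, hgvs_p).
PIK3CA_HOTSPOTS: dict[str, tuple[str, int, str, str, str, str]] = {
    "p.Asn345Lys": ("chr3", 178_916_876, "T", "A", "c.1035T>A", "p.Asn345Lys"),
    "p.Glu545Lys": ("chr3", 178_936_091, "G", "A", "c.1633G>A", "p.Glu545Lys"),
    "p.His1047Arg": ("chr3", 178_952_085, "A", "G", "c.3140A>G", "p.His1047Arg"),
    "p.His1047Leu": ("chr3", 178_952_085, "A", "T", "c.3140A>T", "p.His1047Leu"),
    "p.Gly1049Arg": ("chr3", 178_952_090, "G", "C", "c.3145G>C", "p.Gly1049Arg"),
}

#: Germline pathogenic variants in breast-cancer predisposition genes:
#: (gene, hgvs_c, hgvs_p, consequence).
GERMLINE_CATALOGUE: list[tuple[str, str, str, str]] = [
    ("PALB2", "c.1984A>T", "p.Lys662Ter", "stop_gained"),
    ("BRCA1", "c.5266dup", "p.Gln1756fs", "frameshift"),
    ("BRCA1", "c.4484G>T", "p.Arg1495Met", "missense"),
    ("BRCA2", "c.6275_6276del", "p.Leu2092fs", "frameshift"),
]

_SOMATIC_GENES = [
    "PIK3CA", "ARID1A", "EP300", "SMO", "SMARCA4", "PAX5", "NCOR1",
    "MAP3K1", "GATA3", "CREBBP", "TRAF7", "TP53", "PIK3R1", "PDGFRA",
    "NOTCH2", "NOTCH1", "FOXL2", "CIC", "BRAF", "AXIN1", "ASXL1",
    "ARID2", "ABL1",
]

_CNV_GENES = [
    "MYC", "CCND1", "FGF19", "FGF3", "FGF4", "CDK4", "MDM2", "ERBB2",
    "FGFR1", "ZNF703", "CCNE1", "AKT2", "EGFR", "AURKA", "GNAS",
    "RPS6KB1", "MCL1", "IGF1R", "KRAS", "MET", "CDK6", "BRD4",
]


def _syn_gene(i: int) -> str:
    return f"SYN{i:03d}"


def _syn_locus(i: int) -> tuple[str, int]:
    chrom = f"chr{(i % 22) + 1}"
    return chrom, 2_000_000 + (i // 22 + 1) * 600_000


def default_panel() -> PanelDefinition:
    """Synthetic stand-in for the 523-gene assay (59 CNV-eligible genes)."""
    real = sorted(set(_SOMATIC_GENES) | set(_CNV_GENES) | {"BRCA1", "BRCA2", "PALB2"})
    n_filler = 523 - len(real)
    filler = [_syn_gene(i) for i in range(1, n_filler + 1)]
    cnv_filler = [_syn_gene(i) for i in range(1, 59 - len(_CNV_GENES) + 1)]
    return PanelDefinition(
        gene_list=frozenset(real + filler),
        cnv_gene_list=frozenset(_CNV_GENES + cnv_filler),
        target_size_mb=1.94,
        msi_locus_count=125,
    )


#: Driver spike-in catalogue: the five PIK3CA hotspots plus three recurrent
#: variants per other somatic panel gene.
def _driver_catalogue() -> list[dict]:
    cat = []
    for hgvs_p, (chrom, pos, ref, alt, hgvs_c, _) in sorted(PIK3CA_HOTSPOTS.items()):
        cat.append(
            dict(
                gene="PIK3CA", chrom=chrom, pos=pos, ref=ref, alt=alt,
                consequence="missense", hgvs_c=hgvs_c, hgvs_p=hgvs_p,
            )
        )
    for gene in _SOMATIC_GENES:
        if gene == "PIK3CA":
            continue
        chrom, base = GENE_LOCI[gene]
        for k in range(3):
            codon = 120 + 37 * k
            cat.append(
                dict(
                    gene=gene, chrom=chrom, pos=base + 1000 + 311 * k,
                    ref="C", alt="T", consequence="missense",
                    hgvs_c=f"c.{3 * codon - 1}C>T", hgvs_p=f"p.Ala{codon}Val",
                )
            )
    return cat


# ---------------------------------------------------------------------------
# random simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort simulator parameters; defaults mirror the modelled study.

    Cellularity spans 50-90% (driver VAF ~ cellularity/2); one to five
    drivers per sample; roughly a quarter of samples carry a germline
    pathogenic variant, half of those with allelic imbalance; the gain rate
    reproduces ~54 gains over 15 samples x 59 genes; about 2 in 15 samples
    are MSI-high with 30% of loci shifted.
    """

    n_samples: int = 15
    seed: int = 0
    drivers_min: int = 1
    drivers_max: int = 5
    cellularity_range: tuple[float, float] = (0.50, 0.90)
    driver_vaf_sd: float = 0.03
    artifact_rate: float = 3.0
    artifact_vaf_range: tuple[float, float] = (0.01, 0.05)
    germline_carrier_fraction: float = 4 / 15
    loh_fraction_among_carriers: float = 0.5
    loh_vaf_margin: float = 0.07
    cnv_gain_rate: float = 0.061
    cnv_gain_fc_scale: float = 0.7
    cnv_fc_max: float = 6.0
    msi_high_fraction: float = 2 / 15
    msi_unstable_fraction_high: float = 0.30
    msi_low_instability_rate: float = 0.01
    locus_coverage_mean: float = 150.0
    stutter_off_ref_range: tuple[float, float] = (0.04, 0.12)
    unstable_shift_range: tuple[float, float] = (0.45, 0.65)
    tmb_eligible_mean: float = 8.0
    depth_range: tuple[int, int] = (120, 800)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 1 <= self.drivers_min <= self.drivers_max:
            raise ValueError("need 1 <= drivers_min <= drivers_max")
        for name in (
            "germline_carrier_fraction",
            "loh_fraction_among_carriers",
            "cnv_gain_rate",
            "msi_high_fraction",
            "msi_unstable_fraction_high",
            "msi_low_instability_rate",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.cellularity_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("cellularity_range must be within (0, 1]")
        lo, hi = self.artifact_vaf_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("artifact_vaf_range must be within (0, 1)")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")


@dataclass
class GroundTruth:
    """Per-sample labels of everything the simulator implanted."""

    drivers: dict[str, list[tuple[str, int, str, str]]] = field(default_factory=dict)
    artifacts: dict[str, list[tuple[str, int, str, str]]] = field(default_factory=dict)
    germline: dict[str, list[dict]] = field(default_factory=dict)
    cnv_gains: dict[str, dict[str, float]] = field(default_factory=dict)
    msi_stratum: dict[str, str] = field(default_factory=dict)
    tmb_eligible_count: dict[str, int] = field(default_factory=dict)
    tmb_stratum: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("drivers", "artifacts"):
            d[key] = {s: [list(k) for k in ks] for s, ks in d[key].items()}
        return d


@dataclass
class SimulatedCohort:
    panel: PanelDefinition
    variants: dict[str, list[AnnotatedVariant]]
    cnv_calls: dict[str, list[CnvCall]]
    msi_observations: dict[str, list[MsiLocusObservation]]
    metas: list[SampleMeta]
    truth: GroundTruth

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.metas]


def _stutter_baseline(ref_len: int, off: float) -> dict[int, float]:
    return {ref_len: 1.0 - off, ref_len - 1: 0.75 * off, ref_len + 1: 0.25 * off}


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort in memory; ``cfg.seed`` fully determines the output."""
    rng = np.random.default_rng(cfg.seed)
    panel = default_panel()
    catalogue = _driver_catalogue()
    n_filler = 523 - len(
        set(_SOMATIC_GENES) | set(_CNV_GENES) | {"BRCA1", "BRCA2", "PALB2"}
    )
    filler_genes = [_syn_gene(i) for i in range(1, n_filler + 1)]
    cnv_genes = sorted(panel.cnv_gene_list)

    # shared locus panel: repeat lengths, stutter baselines (fixed per cohort)
    ref_lens = rng.integers(10, 26, size=panel.msi_locus_count)
    offs = rng.uniform(*cfg.stutter_off_ref_range, size=panel.msi_locus_count)
    baselines = [
        _stutter_baseline(int(L), float(o)) for L, o in zip(ref_lens, offs)
    ]

    truth = GroundTruth()
    variants: dict[str, list[AnnotatedVariant]] = {}
    cnv_calls: dict[str, list[CnvCall]] = {}
    msi_obs: dict[str, list[MsiLocusObservation]] = {}
    metas: list[SampleMeta] = []
    gl_idx = 0

    for s in range(cfg.n_samples):
        sid = f"S{s + 1:02d}"
        cellularity = rng.uniform(*cfg.cellularity_range)
        sample_variants: list[AnnotatedVariant] = []
        used: set[tuple[str, int, str, str]] = set()

        def depth() -> int:
            return int(rng.integers(cfg.depth_range[0], cfg.depth_range[1]))

        # drivers: hotspot catalogue entries at cellularity-scaled VAF
        n_drivers = int(rng.integers(cfg.drivers_min, cfg.drivers_max + 1))
        picks = rng.choice(len(catalogue), size=n_drivers, replace=False)
        truth.drivers[sid] = []
        for idx in sorted(picks):
            entry = catalogue[idx]
            key = (entry["chrom"], entry["pos"], entry["ref"], entry["alt"])
            if key in used:
                continue
            used.add(key)
            vaf = float(
                np.clip(rng.normal(cellularity / 2, cfg.driver_vaf_sd), 0.01, 0.99)
            )
            sample_variants.append(
                AnnotatedVariant(
                    sample_id=sid, chrom=entry["chrom"], pos=entry["pos"],
                    ref=entry["ref"], alt=entry["alt"], gene=entry["gene"],
                    consequence=entry["consequence"], vaf=round(vaf, 6),
                    depth=depth(), popmax_af=None, cgc_somatic=True,
                    cosmic_pathogenic=True, filter_status="PASS",
                    hgvs_c=entry["hgvs_c"], hgvs_p=entry["hgvs_p"],
                )
            )
            truth.drivers[sid].append(key)

        def random_locus() -> tuple[str, int, str, str, str]:
            while True:
                gi = int(rng.integers(0, len(filler_genes)))
                gene = filler_genes[gi]
                chrom, base = _syn_locus(gi + 1)
                pos = base + int(rng.integers(1, 400_000))
                ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
                if (chrom, pos, ref, alt) not in used:
                    used.add((chrom, pos, ref, alt))
                    return gene, chrom, pos, ref, alt

        # FFPE artifacts: low-VAF deamination-like C>T / G>A changes
        n_artifacts = int(rng.poisson(cfg.artifact_rate))
        truth.artifacts[sid] = []
        for _ in range(n_artifacts):
            gene, chrom, pos, ref, alt = random_locus()
            vaf = float(rng.uniform(*cfg.artifact_vaf_range))
            sample_variants.append(
                AnnotatedVariant(
                    sample_id=sid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                    gene=gene, consequence="missense", vaf=round(vaf, 6),
                    depth=depth(), popmax_af=None, cgc_somatic=False,
                    cosmic_pathogenic=False, filter_status="PASS",
                )
            )
            truth.artifacts[sid].append((chrom, pos, ref, alt))

        # TMB-eligible passenger variants (coding, non-hotspot)
        n_eligible = int(rng.poisson(cfg.tmb_eligible_mean))
        for _ in range(n_eligible):
            gene, chrom, pos, ref, alt = random_locus()
            csq = "synonymous" if rng.random() < 0.5 else "missense"
            vaf = float(rng.uniform(0.10, 0.60))
            sample_variants.append(
                AnnotatedVariant(
                    sample_id=sid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                    gene=gene, consequence=csq, vaf=round(vaf, 6),
                    depth=depth(), popmax_af=None, cgc_somatic=False,
                    cosmic_pathogenic=False, filter_status="PASS",
                )
            )
        truth.tmb_eligible_count[sid] = n_eligible
        truth.tmb_stratum[sid] = (
            "high" if n_eligible / panel.target_size_mb >= 10.0 else "low"
        )

        # germline carrier with optional allelic imbalance
        germline_meta: list[tuple[str, str, str]] = []
        truth.germline[sid] = []
        if rng.random() < cfg.germline_carrier_fraction:
            gene, hgvs_c, hgvs_p, csq = GERMLINE_CATALOGUE[
                gl_idx % len(GERMLINE_CATALOGUE)
            ]
            gl_idx += 1
            loh = rng.random() < cfg.loh_fraction_among_carriers
            if loh:
                vaf = float(rng.uniform(0.5 + cfg.loh_vaf_margin, 0.85))
            else:
                vaf = float(rng.uniform(0.40, 0.50))
            chrom, base = GENE_LOCI[gene]
            pos = base + 500 + gl_idx
            ref, alt = ("A", "T")
            used.add((chrom, pos, ref, alt))
            sample_variants.append(
                AnnotatedVariant(
                    sample_id=sid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                    gene=gene, consequence=csq, vaf=round(vaf, 6), depth=depth(),
                    popmax_af=None, cgc_somatic=False, cosmic_pathogenic=False,
                    filter_status="PASS", hgvs_c=hgvs_c, hgvs_p=hgvs_p,
                    origin="known_germline",
                )
            )
            germline_meta.append((gene, hgvs_c, hgvs_p))
            truth.germline[sid].append(
                {"gene": gene, "hgvs_c": hgvs_c, "hgvs_p": hgvs_p, "loh": bool(loh)}
            )

        variants[sid] = sample_variants

        # CNV fold-changes for the 59 eligible genes
        calls = []
        truth.cnv_gains[sid] = {}
        for gene in cnv_genes:
            if rng.random() < cfg.cnv_gain_rate:
                fc = float(
                    min(1.5 + rng.exponential(cfg.cnv_gain_fc_scale), cfg.cnv_fc_max)
                )
                truth.cnv_gains[sid][gene] = round(fc, 4)
            else:
                fc = float(np.clip(rng.normal(1.0, 0.08), 0.7, 1.3))
            calls.append(CnvCall(sid, gene, round(fc, 4)))
        cnv_calls[sid] = calls

        # MSI locus histograms
        is_high = rng.random() < cfg.msi_high_fraction
        if is_high:
            k = int(round(cfg.msi_unstable_fraction_high * panel.msi_locus_count))
            unstable_idx = set(
                rng.choice(panel.msi_locus_count, size=k, replace=False).tolist()
            )
        else:
            unstable_idx = {
                i
                for i in range(panel.msi_locus_count)
                if rng.random() < cfg.msi_low_instability_rate
            }
        obs_list = []
        n_assessed = 0
        n_unstable_assessed = 0
        for li in range(panel.msi_locus_count):
            coverage = int(rng.poisson(cfg.locus_coverage_mean))
            L = int(ref_lens[li])
            base = baselines[li]
            if li in unstable_idx:
                shift = rng.uniform(*cfg.unstable_shift_range)
                probs = {
                    L: max(0.0, base[L] - shift),
                    L - 1: base[L - 1],
                    L + 1: base[L + 1],
                    L - 2: 0.6 * shift,
                    L - 3: 0.4 * shift,
                }
            else:
                probs = dict(base)
            lengths = sorted(probs)
            p = np.array([probs[l] for l in lengths])
            p = p / p.sum()
            counts = rng.multinomial(coverage, p)
            hist = {l: int(c) for l, c in zip(lengths, counts) if c > 0}
            if not hist:
                hist = {L: 0}
            obs_list.append(
                MsiLocusObservation(
                    sample_id=sid, locus_id=f"L{li + 1:03d}",
                    reference_repeat_length=L,
                    read_length_histogram=hist, baseline_histogram=base,
                )
            )
            if coverage >= 60:
                n_assessed += 1
                if li in unstable_idx:
                    n_unstable_assessed += 1
        msi_obs[sid] = obs_list
        if n_assessed == 0:
            truth.msi_stratum[sid] = "not_evaluable"
        elif n_unstable_assessed == 0:
            truth.msi_stratum[sid] = "stable"
        elif 100.0 * n_unstable_assessed / n_assessed >= 10.0:
            truth.msi_stratum[sid] = "high"
        else:
            truth.msi_stratum[sid] = "low"

        metas.append(
            SampleMeta(
                sample_id=sid,
                er="positive" if rng.random() < 0.87 else "negative",
                pr="positive" if rng.random() < 0.93 else "negative",
                her2="negative" if rng.random() < 0.79 else "positive",
                ar="positive",
                germline_variants=tuple(germline_meta),
            )
        )

    return SimulatedCohort(
        panel=panel,
        variants=variants,
        cnv_calls=cnv_calls,
        msi_observations=msi_obs,
        metas=metas,
        truth=truth,
    )


def write_cohort(
    cohort: SimulatedCohort, out_dir: str | Path, comments: tuple[str, ...] = ()
) -> None:
    """Write a cohort in the io_model formats (one VCF per sample, shared
    CNV/MSI/meta TSVs, panel gene lists and a ground-truth JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid in cohort.sample_ids:
        write_variants(cohort.variants[sid], out / f"{sid}.vcf", sample_id=sid)
    all_cnv = [c for sid in cohort.sample_ids for c in cohort.cnv_calls[sid]]
    write_cnv_table(all_cnv, out / "cnv.tsv", comments)
    all_msi = [o for sid in cohort.sample_ids for o in cohort.msi_observations[sid]]
    write_msi_table(all_msi, out / "msi.tsv", comments)
    write_sample_meta(cohort.metas, out / "meta.tsv", comments)
    write_panel(cohort.panel, out / "panel_genes.txt", out / "panel_cnv_genes.txt")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# the 15-sample study fixture
# ---------------------------------------------------------------------------

# per-sample somatic drivers: gene and class; "hotspot:<p.>" marks one of the
# five PIK3CA hotspot alterations
_FIXTURE_SOMATIC: dict[int, list[tuple[str, str]]] = {
    1: [("ARID1A", "missense"), ("ARID1A", "frameshift"), ("EP300", "missense"),
        ("SMO", "missense"), ("TP53", "stop_gained")],
    2: [("PIK3CA", "hotspot:p.Gly1049Arg"), ("SMO", "missense"),
        ("SMARCA4", "missense"), ("PIK3R1", "missense")],
    3: [("PIK3CA", "hotspot:p.His1047Arg"), ("EP300", "missense"),
        ("SMARCA4", "missense"), ("PAX5", "missense"), ("NCOR1", "missense")],
    4: [("GATA3", "frameshift"), ("NOTCH1", "stop_gained")],
    5: [("EP300", "missense"), ("PAX5", "missense"), ("PDGFRA", "missense")],
    6: [("ARID2", "frameshift")],
    7: [("PIK3CA", "hotspot:p.His1047Leu"), ("FOXL2", "missense")],
    8: [("ARID1A", "missense"), ("MAP3K1", "missense"), ("GATA3", "missense"),
        ("CREBBP", "missense"), ("TRAF7", "missense")],
    9: [("ABL1", "missense")],
    10: [("PIK3CA", "hotspot:p.Asn345Lys"), ("CIC", "missense")],
    11: [("PIK3CA", "hotspot:p.Glu545Lys"), ("BRAF", "missense")],
    12: [("NCOR1", "missense"), ("MAP3K1", "missense"), ("NOTCH2", "missense")],
    13: [("ARID1A", "missense")],
    14: [("CREBBP", "missense"), ("AXIN1", "missense")],
    15: [("PIK3CA", "hotspot:p.His1047Arg"), ("ASXL1", "missense")],
}

# germline carriers: sample -> (catalogue index, tumor VAF, LOH truth);
# tumor VAFs are fixture-invented, consistent with the printed LOH statuses
_FIXTURE_GERMLINE: dict[int, tuple[int, float, bool]] = {
    1: (0, 0.72, True),    # PALB2 p.Lys662Ter, LOH
    4: (1, 0.44, False),   # BRCA1 p.Gln1756fs, NO LOH
    5: (2, 0.67, True),    # BRCA1 p.Arg1495Met, LOH
    12: (3, 0.48, False),  # BRCA2 p.Leu2092fs, NO LOH
}

# copy-number gains: gene, cytoband, {sample -> fold_change}; 54 gains in 22
# genes across 13 samples, per-gene medians as published
_FIXTURE_CNV_GAINS: list[tuple[str, str, dict[int, float]]] = [
    ("MYC", "8q24.21", {1: 1.8, 2: 1.8, 3: 1.9, 4: 1.9, 5: 1.9, 7: 2.0, 8: 3.0, 10: 3.8}),
    ("CCND1", "11q13.3", {2: 2.0, 3: 3.0, 8: 3.7, 11: 4.0, 12: 5.2}),
    ("FGF19", "11q13.3", {3: 1.8, 8: 2.2, 11: 2.6, 14: 3.1}),
    ("FGF3", "11q13.3", {3: 1.9, 8: 2.9, 11: 3.5}),
    ("FGF4", "11q13.3", {3: 5.6, 8: 6.2}),
    ("CDK4", "12q14.1", {1: 1.8, 5: 2.9, 12: 3.3}),
    ("MDM2", "12q15", {1: 1.7, 5: 2.7, 12: 3.1, 15: 3.6}),
    ("ERBB2", "17q12", {4: 2.1, 7: 2.5, 10: 3.0}),
    ("FGFR1", "8p11.23", {1: 1.8, 8: 2.3, 14: 2.9}),
    ("ZNF703", "8p11.23", {1: 1.9, 8: 2.4, 14: 3.1}),
    ("CCNE1", "19q12", {2: 1.7, 5: 2.2, 12: 2.8}),
    ("AKT2", "19q13.2", {3: 1.6, 10: 2.0, 15: 2.6}),
    ("EGFR", "7p11.2", {7: 2.2}),
    ("AURKA", "20q13.2", {13: 1.9}),
    ("GNAS", "20q13.32", {11: 2.0}),
    ("RPS6KB1", "17q23.1", {12: 2.4}),
    ("MCL1", "1q21.3", {1: 1.7}),
    ("IGF1R", "15q26.3", {5: 1.8}),
    ("KRAS", "12p12.1", {2: 2.1}),
    ("MET", "7q31.2", {10: 1.6}),
    ("CDK6", "7q21.2", {15: 1.8}),
    ("BRD4", "19p13.12", {4: 1.7}),
]

# TMB-eligible passenger counts; 24 and 23 put samples 1 and 3 above the
# 10 mut/Mb cutoff on a 1.94 Mb panel
_FIXTURE_TMB_COUNTS = {
    1: 24, 2: 4, 3: 23, 4: 6, 5: 8, 6: 2, 7: 9, 8: 10, 9: 3, 10: 7,
    11: 8, 12: 12, 13: 5, 14: 6, 15: 14,
}

# unstable homopolymer loci per sample; sample 1 has no locus at the
# 60-read coverage gate (MSI not evaluable), sample 8 has six below it
_FIXTURE_MSI_UNSTABLE = {
    1: 0, 2: 22, 3: 4, 4: 3, 5: 0, 6: 0, 7: 5, 8: 17, 9: 0, 10: 3,
    11: 3, 12: 4, 13: 0, 14: 0, 15: 1,
}

# ER, PR, HER2 exactly as printed; AR/TILs/subtype marginals match the
# published clinical table (per-sample assignment fixture-invented)
_FIXTURE_META: dict[int, dict] = {
    1: dict(er="negative", pr="positive", her2=None, ar=None, grade=3,
            tnm_stage=None, ki67_class="high", intrinsic_subtype=None,
            tils_percent=None),
    2: dict(er="positive", pr="positive", her2="negative", ar="positive", grade=2,
            tnm_stage="I", ki67_class="high",
            intrinsic_subtype="Luminal-B/HER2-negative", tils_percent=0.0),
    3: dict(er="positive", pr="positive", her2="negative", ar="positive", grade=3,
            tnm_stage="II", ki67_class="high",
            intrinsic_subtype="Luminal-B/HER2-negative", tils_percent=0.0),
    4: dict(er="negative", pr="negative", her2="positive", ar="positive", grade=3,
            tnm_stage="III", ki67_class="high",
            intrinsic_subtype="HER2-enriched", tils_percent=70.0),
    5: dict(er="positive", pr="positive", her2="negative", ar="positive", grade=2,
            tnm_stage="II", ki67_class="low",
            intrinsic_subtype="Luminal-B/HER2-negative", tils_percent=5.0),
    6: dict(er="positive", pr="positive", her2="negative", ar="positive", grade=2,
            tnm_stage="I", ki67_class="high",
            intrinsic_subtype="Luminal-B/HER2-negative", tils_percent=5.0),
    7: dict(er="positive", pr="positive", her2="positive", ar="positive", grade=3,
            tnm_stage="III", ki67_class="high",
            intrinsic_subtype="Luminal-B/HER2-positive", tils_percent=10.0),
    8: dict(er="positive", pr="positive", her2="negative", ar="positive", grade=3,
            tnm_stage="II", ki67_class="high",
            intrinsic_subtype="Luminal-B/HER2-negative", tils_percent=10.0),
    9: dict(er="positive", pr="positive", her2="negative", ar="positive", grade=2,
            tnm_stage="I", ki67_class="low",
            intrinsic_subtype="Luminal-A", tils_percent=10.0),
    10: dict(er="positive", pr="positive", her2="negative", ar="positive", grade=2,
             tnm_stage="I", ki67_class="high",
             intrinsic_subtype="Luminal-B/HER2-negative", tils_percent=10.0),
    11: dict(er="positive", pr="positive", her2="negative", ar="positive", grade=3,
             tnm_stage="III", ki67_class="high",
             intrinsic_subtype="Luminal-B/HER2-negative", tils_percent=15.0),
    12: dict(er="positive", pr="positive", her2="positive", ar="positive", grade=3,
             tnm_stage="III", ki67_class="high",
             intrinsic_subtype="Luminal-B/HER2-positive", tils_percent=20.0),
    13: dict(er="positive", pr="positive", her2="negative", ar="positive", grade=2,
             tnm_stage="I", ki67_class="low",
             intrinsic_subtype="Luminal-A", tils_percent=25.0),
    14: dict(er="positive", pr="positive", her2="negative", ar="positive", grade=2,
             tnm_stage="I", ki67_class="low",
             intrinsic_subtype="Luminal-A", tils_percent=30.0),
    15: dict(er="positive", pr="positive", her2="negative", ar="positive", grade=3,
             tnm_stage="III", ki67_class="high",
             intrinsic_subtype="Luminal-B/HER2-negative", tils_percent=40.0),
}

_FIXTURE_COMMENTS = (
    "synthetic fixture of the published 15-sample male breast cancer cohort",
    "printed values (germline variants, LOH, hotspot alterations, strata,",
    "receptor statuses, gene/CNV frequencies) are encoded literally;",
    "per-variant VAFs/depths and locus histograms are fixture-invented",
)


def _fixture_sample_id(n: int) -> str:
    return f"MBC{n:02d}"


def _fixture_somatic_variant(
    sid: str, n: int, gene: str, kind: str, idx: int
) -> AnnotatedVariant:
    if kind.startswith("hotspot:"):
        chrom, pos, ref, alt, hgvs_c, hgvs_p = PIK3CA_HOTSPOTS[kind.split(":", 1)[1]]
        consequence = "missense"
    else:
        consequence = kind
        chrom, base = GENE_LOCI[gene]
        pos = base + 1000 + 137 * (idx + 1)
        codon = 100 + idx
        if consequence == "missense":
            ref, alt = "C", "T"
            hgvs_c, hgvs_p = f"c.{3 * codon}C>T", f"p.Ala{codon}Val"
        elif consequence == "stop_gained":
            ref, alt = "C", "A"
            hgvs_c, hgvs_p = f"c.{3 * codon}C>A", f"p.Gln{codon}Ter"
        else:  # frameshift deletion
            ref, alt = "CA", "C"
            hgvs_c, hgvs_p = f"c.{3 * codon}del", f"p.Lys{codon}fs"
    vaf = 0.12 + 0.03 * ((n * 7 + idx * 3) % 12)
    depth = 150 + 37 * ((n + idx) % 12)
    return AnnotatedVariant(
        sample_id=sid, chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        consequence=consequence, vaf=round(vaf, 6), depth=depth, popmax_af=None,
        cgc_somatic=True, cosmic_pathogenic=True, filter_status="PASS",
        hgvs_c=hgvs_c, hgvs_p=hgvs_p,
    )


def emit_paper_fixture(out_dir: str | Path | None = None) -> SimulatedCohort:
    """The deterministic 15-sample fixture cohort.

    Encodes the published per-sample actionability table and cohort counts:
    four germline carriers (two with LOH), six samples with PIK3CA hotspot
    drivers, 40 somatic drivers in 24 genes, 54 copy-number gains in 22
    genes across 13 samples, two TMB-high and two MSI-high samples, and an
    MSI-not-evaluable sample 1.
    """
    panel = default_panel()
    truth = GroundTruth()
    variants: dict[str, list[AnnotatedVariant]] = {}
    cnv_calls: dict[str, list[CnvCall]] = {}
    msi_obs: dict[str, list[MsiLocusObservation]] = {}
    metas: list[SampleMeta] = []

    n_filler = 523 - len(
        set(_SOMATIC_GENES) | set(_CNV_GENES) | {"BRCA1", "BRCA2", "PALB2"}
    )
    filler_genes = [_syn_gene(i) for i in range(1, n_filler + 1)]

    gains_by_sample: dict[int, list[tuple[str, str, float]]] = {n: [] for n in range(1, 16)}
    for gene, cytoband, per_sample in _FIXTURE_CNV_GAINS:
        for n, fc in per_sample.items():
            gains_by_sample[n].append((gene, cytoband, fc))

    for n in range(1, 16):
        sid = _fixture_sample_id(n)
        sample_variants: list[AnnotatedVariant] = []

        # somatic drivers
        truth.drivers[sid] = []
        for idx, (gene, kind) in enumerate(_FIXTURE_SOMATIC[n]):
            v = _fixture_somatic_variant(sid, n, gene, kind, idx)
            sample_variants.append(v)
            truth.drivers[sid].append(v.key)
        truth.artifacts[sid] = []

        # germline variant with LOH-consistent tumor VAF
        germline_meta: list[tuple[str, str, str]] = []
        truth.germline[sid] = []
        if n in _FIXTURE_GERMLINE:
            cat_idx, vaf, loh = _FIXTURE_GERMLINE[n]
            gene, hgvs_c, hgvs_p, csq = GERMLINE_CATALOGUE[cat_idx]
            chrom, base = GENE_LOCI[gene]
            sample_variants.append(
                AnnotatedVariant(
                    sample_id=sid, chrom=chrom, pos=base + 500 + cat_idx,
                    ref="A", alt="T", gene=gene, consequence=csq, vaf=vaf,
                    depth=300, popmax_af=None, cgc_somatic=False,
                    cosmic_pathogenic=False, filter_status="PASS",
                    hgvs_c=hgvs_c, hgvs_p=hgvs_p, origin="known_germline",
                )
            )
            germline_meta.append((gene, hgvs_c, hgvs_p))
            truth.germline[sid].append(
                {"gene": gene, "hgvs_c": hgvs_c, "hgvs_p": hgvs_p, "loh": loh}
            )

        # TMB-eligible passengers (synonymous, non-hotspot)
        count = _FIXTURE_TMB_COUNTS[n]
        for j in range(count):
            gi = (n * 11 + j * 5) % len(filler_genes)
            gene = filler_genes[gi]
            chrom, base = _syn_locus(gi + 1)
            pos = base + 997 * (j + 1) + n
            sample_variants.append(
                AnnotatedVariant(
                    sample_id=sid, chrom=chrom, pos=pos, ref="C", alt="T",
                    gene=gene, consequence="synonymous",
                    vaf=round(0.10 + 0.02 * (j % 15), 6),
                    depth=100 + 11 * (j % 30), popmax_af=None,
                    cgc_somatic=False, cosmic_pathogenic=False,
                    filter_status="PASS",
                )
            )
        truth.tmb_eligible_count[sid] = count
        truth.tmb_stratum[sid] = (
            "high" if count / panel.target_size_mb >= 10.0 else "low"
        )
        variants[sid] = sample_variants

        # CNV: listed gains plus near-diploid fold-changes for the rest
        gained = {g for g, _, _ in gains_by_sample[n]}
        calls = [
            CnvCall(sid, gene, fc, cytoband)
            for gene, cytoband, fc in sorted(gains_by_sample[n])
        ]
        for gi, gene in enumerate(sorted(panel.cnv_gene_list)):
            if gene in gained:
                continue
            fc = 0.9 + 0.01 * ((n * 7 + gi * 3) % 21)
            calls.append(CnvCall(sid, gene, round(fc, 4)))
        cnv_calls[sid] = calls
        truth.cnv_gains[sid] = {g: fc for g, _, fc in gains_by_sample[n]}

        # MSI locus table
        n_unstable = _FIXTURE_MSI_UNSTABLE[n]
        obs_list = []
        below_gate = 125 if n == 1 else (6 if n == 8 else 0)
        unstable_set = set(range(below_gate, below_gate + n_unstable))
        n_assessed = 0
        for li in range(125):
            L = 10 + (li % 15)
            off = 0.04 + (li % 9) * 0.01
            base = _stutter_baseline(L, off)
            if li < below_gate:
                coverage = 30 + (li * 7) % 25
            else:
                coverage = 100 + (li * 13 + n * 7) % 80
            if li in unstable_set:
                n_m1 = round(0.75 * off * coverage)
                n_p1 = round(0.25 * off * coverage)
                n_m2 = round(0.27 * coverage)
                n_m3 = round(0.18 * coverage)
                hist = {
                    L: coverage - n_m1 - n_p1 - n_m2 - n_m3,
                    L - 1: n_m1, L + 1: n_p1, L - 2: n_m2, L - 3: n_m3,
                }
            else:
                n_m1 = round(0.75 * off * coverage)
                n_p1 = round(0.25 * off * coverage)
                hist = {L: coverage - n_m1 - n_p1, L - 1: n_m1, L + 1: n_p1}
            obs_list.append(
                MsiLocusObservation(
                    sample_id=sid, locus_id=f"L{li + 1:03d}",
                    reference_repeat_length=L,
                    read_length_histogram={k: v for k, v in hist.items() if v > 0},
                    baseline_histogram=base,
                )
            )
            if coverage >= 60:
                n_assessed += 1
        msi_obs[sid] = obs_list
        if n_assessed == 0:
            truth.msi_stratum[sid] = "not_evaluable"
        elif n_unstable == 0:
            truth.msi_stratum[sid] = "stable"
        elif 100.0 * n_unstable / n_assessed >= 10.0:
            truth.msi_stratum[sid] = "high"
        else:
            truth.msi_stratum[sid] = "low"

        metas.append(
            SampleMeta(
                sample_id=sid,
                germline_variants=tuple(germline_meta),
                **_FIXTURE_META[n],
            )
        )

    cohort = SimulatedCohort(
        panel=panel, variants=variants, cnv_calls=cnv_calls,
        msi_observations=msi_obs, metas=metas, truth=truth,
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir, _FIXTURE_COMMENTS)
    return cohort
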