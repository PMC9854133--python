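"""Domain types and readers/writers for tumor-only panel profiling.

The pipeline consumes the outputs of upstream variant/CNV/MSI callers; this
module defines the in-memory types for those inputs and the on-disk formats:

* annotated somatic calls — VCF 4.2 with a fixed INFO-tag convention
  (``GENE``, ``CSQ``, ``VAF``, ``DP``, ``PMAF``, ``CGC``, ``COSM``,
  ``HGVSC``, ``HGVSP``, ``ORIGIN``; see :data:`INFO_TAGS`),
* gene-level copy-number fold-changes — TSV,
* homopolymer-locus read-length histograms with stutter baselines — TSV,
* sample clinical metadata — TSV,
* panel definition — gene list + BED,
* analysis thresholds — YAML.

Coordinate conventions are centralized here: VCF positions are 1-based
inclusive, BED intervals are 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
import yaml

__all__ = [
    "FormatError",
    "SchemaError",
    "CONSEQUENCES",
    "STATUS_VALUES",
    "ORIGINS",
    "PanelDefinition",
    "AnnotatedVariant",
    "CnvCall",
    "MsiLocusObservation",
    "SampleMeta",
    "ThresholdConfig",
    "read_variants",
    "write_variants",
    "read_cnv_table",
    "write_cnv_table",
    "read_msi_table",
    "write_msi_table",
    "read_sample_meta",
    "write_sample_meta",
    "read_threshold_config",
    "write_threshold_config",
    "read_panel",
    "write_panel",
    "bed_to_vcf_interval",
    "vcf_to_bed_interval",
    "chrom_sort_key",
]


class FormatError(ValueError):
    """A file could not be parsed in its declared format."""


class SchemaError(ValueError):
    """A file parsed, but violates the documented column/tag schema."""


#: Controlled consequence vocabulary.
CONSEQUENCES = frozenset(
    {
        "missense",
        "synonymous",
        "stop_gained",
        "frameshift",
        "inframe_indel",
        "splice_site",
        "intronic",
        "other",
    }
)

#: Receptor-status vocabulary ("missing" is represented as None in memory).
STATUS_VALUES = frozenset({"positive", "negative"})

ORIGINS = frozenset({"somatic_candidate", "known_germline"})


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural ordering for human chromosome names (chr1 < chr2 < ... < chrX)."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c.isdigit():
        return (int(c), "")
    return (100, c)


def bed_to_vcf_interval(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open BED interval to 1-based inclusive."""
    return start0 + 1, end0


def vcf_to_bed_interval(pos1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open BED."""
    return pos1 - 1, end1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelDefinition:
    """A targeted sequencing panel.

    Parameters
    ----------
    gene_list
        All genes covered by the panel (523 for the full assay modelled here).
    cnv_gene_list
        Subset of genes for which the upstream copy-number caller emits
        fold-changes (59 for the full assay).
    target_size_mb
        Megabases of targeted genome, the TMB denominator. Default 1.94.
    msi_locus_count
        Number of homopolymer microsatellite loci interrogated. Default 125.
    """

    gene_list: frozenset[str]
    cnv_gene_list: frozenset[str]
    target_size_mb: float = 1.94
    msi_locus_count: int = 125

    def __post_init__(self) -> None:
        if not self.cnv_gene_list <= self.gene_list:
            extra = sorted(self.cnv_gene_list - self.gene_list)
            raise ValueError(f"cnv_gene_list not a subset of gene_list: {extra[:5]}")
        if self.target_size_mb <= 0:
            raise ValueError("target_size_mb must be > 0")
        if self.msi_locus_count <= 0:
            raise ValueError("msi_locus_count must be > 0")


@dataclass(frozen=True)
class AnnotatedVariant:
    """One annotated somatic candidate call (one ALT allele of one record)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    vaf: float
    depth: int
    popmax_af: float | None = None
    cgc_somatic: bool = False
    cosmic_pathogenic: bool = False
    filter_status: str = "PASS"
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    origin: str = "somatic_candidate"

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.popmax_af is not None and not 0.0 <= self.popmax_af <= 1.0:
            raise ValueError("popmax_af outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CnvCall:
    """Gene-level copy-number fold-change (1.0 = diploid baseline)."""

    sample_id: str
    gene: str
    fold_change: float
    cytoband: str | None = None

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")


@dataclass(frozen=True)
class MsiLocusObservation:
    """Read-length histogram at one homopolymer locus plus its baseline.

    ``baseline_histogram`` maps repeat length to the expected read
    proportion under the normal stutter model; proportions must sum to 1.
    """

    sample_id: str
    locus_id: str
    reference_repeat_length: int
    read_length_histogram: Mapping[int, int]
    baseline_histogram: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.reference_repeat_length < 1:
            raise ValueError("reference_repeat_length must be >= 1")
        if any(c < 0 for c in self.read_length_histogram.values()):
            raise ValueError("read counts must be >= 0")
        total = sum(self.baseline_histogram.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"baseline proportions sum to {total}, expected 1")

    @property
    def coverage(self) -> int:
        return sum(self.read_length_histogram.values())


@dataclass(frozen=True)
class SampleMeta:
    """Clinical metadata for one sample.

    Receptor statuses are ``"positive"``/``"negative"`` or None (missing).
    ``germline_variants`` lists known germline pathogenic variants as
    (gene, hgvs_c, hgvs_p) tuples.
    """

    sample_id: str
    er: str | None = None
    pr: str | None = None
    her2: str | None = None
    ar: str | None = None
    grade: int | None = None
    tnm_stage: str | None = None
    ki67_class: str | None = None
    intrinsic_subtype: str | None = None
    tils_percent: float | None = None
    germline_variants: tuple[tuple[str, str, str], ...] = ()

    def __post_init__(self) -> None:
        for name in ("er", "pr", "her2", "ar"):
            v = getattr(self, name)
            if v is not None and v not in STATUS_VALUES:
                raise ValueError(f"{name} status {v!r} not in {sorted(STATUS_VALUES)}")


@dataclass(frozen=True)
class ThresholdConfig:
    """All numeric thresholds of the profiling pipeline.

    Defaults reproduce the study conditions: driver VAF window
    [0.05, 0.90], depth >= 40, gnomAD popmax < 0.01, LOH above 0.50 tumor
    VAF, CNV gain at fold-change >= 1.5 and loss at <= 0.5, TMB-high at
    >= 10 mut/Mb, MSI-high at >= 10% unstable sites with a 60-read
    per-locus coverage gate.
    """

    vaf_min: float = 0.05
    vaf_max: float = 0.90
    depth_min: int = 40
    popmax_af_max: float = 0.01
    loh_vaf: float = 0.50
    cnv_gain_fc: float = 1.5
    cnv_loss_fc: float = 0.5
    tmb_high_cutoff: float = 10.0
    msi_high_pct: float = 10.0
    msi_min_coverage: int = 60
    #: Excess off-reference read fraction (over baseline) calling a locus
    #: unstable. Implementation parameter: the vendor per-locus test is
    #: proprietary.
    locus_instability_threshold: float = 0.20
    #: Whether a variant with no population-frequency annotation passes the
    #: popmax filter (rare somatic hotspots are typically absent from gnomAD).
    popmax_missing_passes: bool = True
    #: TMB eligibility toggles (the assay convention counts synonymous coding
    #: variants but excludes database hotspots and known germline variants).
    tmb_include_synonymous: bool = True
    tmb_exclude_hotspots: bool = True
    tmb_exclude_germline: bool = True
    #: Per-locus MSI test: "shift" (excess off-reference fraction) or "js"
    #: (Jensen-Shannon distance to baseline).
    msi_method: str = "shift"

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf_min < self.vaf_max <= 1.0:
            raise ValueError("require 0 <= vaf_min < vaf_max <= 1")
        for name in (
            "depth_min",
            "popmax_af_max",
            "loh_vaf",
            "cnv_gain_fc",
            "cnv_loss_fc",
            "tmb_high_cutoff",
            "msi_high_pct",
            "msi_min_coverage",
            "locus_instability_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.cnv_loss_fc >= self.cnv_gain_fc:
            raise ValueError("cnv_loss_fc must be < cnv_gain_fc")
        if self.msi_method not in ("shift", "js"):
            raise ValueError("msi_method must be 'shift' or 'js'")


def read_threshold_config(path: str | Path) -> ThresholdConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(ThresholdConfig)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown threshold keys: {sorted(unknown)}")
    return ThresholdConfig(**data)


def write_threshold_config(cfg: ThresholdConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# VCF reader / writer
# ---------------------------------------------------------------------------

#: INFO-tag convention for annotated VCFs (tag, Number, Type, description).
INFO_TAGS = [
    ("GENE", "1", "String", "Gene symbol"),
    ("CSQ", "A", "String", "Consequence (controlled vocabulary)"),
    ("VAF", "A", "Float", "Variant allele fraction"),
    ("DP", "1", "Integer", "Total read depth"),
    ("PMAF", "A", "Float", "Global population (popmax) allele frequency"),
    ("CGC", "A", "Integer", "Cancer Gene Census somatic flag (0/1)"),
    ("COSM", "A", "Integer", "COSMIC pathogenic flag (0/1)"),
    ("HGVSC", "A", "String", "Transcript-level HGVS"),
    ("HGVSP", "A", "String", "Protein-level HGVS"),
    ("ORIGIN", "A", "String", "somatic_candidate or known_germline"),
]

MANDATORY_TAGS = ("GENE", "CSQ", "VAF", "DP")

_CONTIGS = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]


def _vcf_header(sample_id: str) -> pysam.VariantHeader:
    hdr = pysam.VariantHeader()
    for contig in _CONTIGS:
        hdr.contigs.add(contig, length=260_000_000)
    for tag, number, vtype, desc in INFO_TAGS:
        hdr.info.add(tag, number, vtype, desc)
    hdr.filters.add("q30", None, None, "Low quality (upstream caller)")
    hdr.add_meta("oncopanel_sample", sample_id)
    return hdr


def _scalar(value):
    """Unwrap pysam's per-allele tuples for single-ALT records."""
    if isinstance(value, tuple):
        return value[0]
    return value


def read_variants(path: str | Path, sample_id: str) -> list[AnnotatedVariant]:
    """Read an annotated VCF into :class:`AnnotatedVariant` records.

    Multi-allelic records are decomposed to one variant per ALT allele; the
    per-allele INFO fields (Number=A) are split accordingly. Missing optional
    annotations become None; a missing mandatory tag raises
    :class:`SchemaError` naming the tag.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read VCF {path}: {exc}") from None
    out: list[AnnotatedVariant] = []
    with vf:
        for rec in vf:
            for tag in MANDATORY_TAGS:
                if tag not in rec.info:
                    raise SchemaError(
                        f"{path}: record {rec.chrom}:{rec.pos} missing mandatory "
                        f"INFO tag {tag}"
                    )
            alts = rec.alts or ()
            n_alt = len(alts)

            def per_alt(tag: str, i: int, default=None):
                if tag not in rec.info:
                    return default
                val = rec.info[tag]
                if isinstance(val, tuple):
                    return val[i] if i < len(val) else default
                return val

            filt = ";".join(rec.filter.keys()) if list(rec.filter.keys()) else "."
            for i, alt in enumerate(alts):
                vaf = per_alt("VAF", i)
                if vaf is None:
                    raise SchemaError(
                        f"{path}: record {rec.chrom}:{rec.pos} allele {alt} "
                        f"missing VAF value"
                    )
                pmaf = per_alt("PMAF", i)
                origin = per_alt("ORIGIN", i) or "somatic_candidate"
                out.append(
                    AnnotatedVariant(
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=str(_scalar(rec.info["GENE"])),
                        consequence=str(per_alt("CSQ", i)),
                        vaf=round(float(vaf), 6),
                        depth=int(rec.info["DP"]),
                        popmax_af=round(float(pmaf), 6) if pmaf is not None else None,
                        cgc_somatic=bool(per_alt("CGC", i, 0)),
                        cosmic_pathogenic=bool(per_alt("COSM", i, 0)),
                        filter_status=filt,
                        hgvs_c=per_alt("HGVSC", i),
                        hgvs_p=per_alt("HGVSP", i),
                        origin=origin,
                    )
                )
            del n_alt
    return out


def write_variants(
    variants: Sequence[AnnotatedVariant], path: str | Path, sample_id: str | None = None
) -> None:
    """Write variants as a single-ALT-per-record annotated VCF."""
    if sample_id is None:
        ids = {v.sample_id for v in variants}
        sample_id = sorted(ids)[0] if ids else "sample"
    hdr = _vcf_header(sample_id)
    ordered = sorted(variants, key=lambda v: (chrom_sort_key(v.chrom), v.pos, v.ref, v.alt))
    with pysam.VariantFile(str(path), "w", header=hdr) as vf:
        for v in ordered:
            rec = vf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            if v.filter_status and v.filter_status != ".":
                for name in v.filter_status.split(";"):
                    if name not in rec.header.filters:
                        rec.header.filters.add(name, None, None, "upstream filter")
                    rec.filter.add(name)
            rec.info["GENE"] = v.gene
            rec.info["CSQ"] = (v.consequence,)
            rec.info["VAF"] = (round(v.vaf, 6),)
            rec.info["DP"] = v.depth
            if v.popmax_af is not None:
                rec.info["PMAF"] = (round(v.popmax_af, 6),)
            rec.info["CGC"] = (int(v.cgc_somatic),)
            rec.info["COSM"] = (int(v.cosmic_pathogenic),)
            if v.hgvs_c:
                rec.info["HGVSC"] = (v.hgvs_c,)
            if v.hgvs_p:
                rec.info["HGVSP"] = (v.hgvs_p,)
            rec.info["ORIGIN"] = (v.origin,)
            vf.write(rec)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read TSV {path}: {exc}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def _write_tsv(df: pd.DataFrame, path: str | Path, comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


CNV_COLUMNS = ["sample_id", "gene", "fold_change", "cytoband"]


def read_cnv_table(path: str | Path) -> list[CnvCall]:
    df = _read_tsv(path, CNV_COLUMNS[:3])
    calls = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            fc = float(row.fold_change)
        except ValueError:
            raise SchemaError(
                f"{path}: row {idx}: bad fold_change {row.fold_change!r}"
            ) from None
        cytoband = getattr(row, "cytoband", "") or None
        try:
            calls.append(CnvCall(row.sample_id, row.gene, fc, cytoband))
        except ValueError as exc:
            raise SchemaError(f"{path}: row {idx}: {exc}") from None
    return calls


def write_cnv_table(
    calls: Sequence[CnvCall], path: str | Path, comments: Sequence[str] = ()
) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "gene": c.gene,
                "fold_change": repr(c.fold_change),
                "cytoband": c.cytoband or "",
            }
            for c in calls
        ],
        columns=CNV_COLUMNS,
    )
    _write_tsv(df, path, comments)


MSI_COLUMNS = ["sample_id", "locus_id", "ref_len", "histogram", "baseline"]

_PAIR_RE = re.compile(r"^\d+:[0-9.eE+-]+$")


def _parse_pairs(text: str, path, idx: int, col: str) -> dict[int, float]:
    pairs: dict[int, float] = {}
    if not text:
        return pairs
    for item in text.split(","):
        if not _PAIR_RE.match(item):
            raise SchemaError(f"{path}: row {idx}: bad {col} entry {item!r}")
        k, v = item.split(":")
        pairs[int(k)] = float(v)
    return pairs


def read_msi_table(path: str | Path) -> list[MsiLocusObservation]:
    df = _read_tsv(path, MSI_COLUMNS)
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        hist = {k: int(v) for k, v in _parse_pairs(row.histogram, path, idx, "histogram").items()}
        base = _parse_pairs(row.baseline, path, idx, "baseline")
        try:
            out.append(
                MsiLocusObservation(
                    sample_id=row.sample_id,
                    locus_id=row.locus_id,
                    reference_repeat_length=int(row.ref_len),
                    read_length_histogram=hist,
                    baseline_histogram=base,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: row {idx}: {exc}") from None
    return out


def _fmt_pairs(mapping: Mapping[int, float], as_int: bool) -> str:
    items = sorted(mapping.items())
    if as_int:
        return ",".join(f"{k}:{int(v)}" for k, v in items)
    return ",".join(f"{k}:{v!r}" for k, v in items)


def write_msi_table(
    observations: Sequence[MsiLocusObservation],
    path: str | Path,
    comments: Sequence[str] = (),
) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": o.sample_id,
                "locus_id": o.locus_id,
                "ref_len": o.reference_repeat_length,
                "histogram": _fmt_pairs(o.read_length_histogram, as_int=True),
                "baseline": _fmt_pairs(o.baseline_histogram, as_int=False),
            }
            for o in observations
        ],
        columns=MSI_COLUMNS,
    )
    _write_tsv(df, path, comments)


META_COLUMNS = [
    "sample_id",
    "er",
    "pr",
    "her2",
    "ar",
    "grade",
    "tnm_stage",
    "ki67_class",
    "intrinsic_subtype",
    "tils_percent",
    "germline_variants",
]

_MISSING = {"", "NA", "n.a.", "."}


def _opt(value: str) -> str | None:
    return None if value in _MISSING else value


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = _read_tsv(path, ["sample_id", "er", "pr", "her2"])
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        gv_text = _opt(getattr(row, "germline_variants", "")) or ""
        germline = []
        for item in filter(None, gv_text.split(";")):
            parts = item.split("|")
            if len(parts) != 3:
                raise SchemaError(
                    f"{path}: row {idx}: bad germline_variants entry {item!r}"
                )
            germline.append(tuple(parts))
        grade = _opt(getattr(row, "grade", ""))
        tils = _opt(getattr(row, "tils_percent", ""))
        try:
            out.append(
                SampleMeta(
                    sample_id=row.sample_id,
                    er=_opt(row.er),
                    pr=_opt(row.pr),
                    her2=_opt(row.her2),
                    ar=_opt(getattr(row, "ar", "")),
                    grade=int(grade) if grade is not None else None,
                    tnm_stage=_opt(getattr(row, "tnm_stage", "")),
                    ki67_class=_opt(getattr(row, "ki67_class", "")),
                    intrinsic_subtype=_opt(getattr(row, "intrinsic_subtype", "")),
                    tils_percent=float(tils) if tils is not None else None,
                    germline_variants=tuple(germline),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: row {idx}: {exc}") from None
    return out


def write_sample_meta(
    metas: Sequence[SampleMeta], path: str | Path, comments: Sequence[str] = ()
) -> None:
    rows = []
    for m in metas:
        rows.append(
            {
                "sample_id": m.sample_id,
                "er": m.er or "NA",
                "pr": m.pr or "NA",
                "her2": m.her2 or "NA",
                "ar": m.ar or "NA",
                "grade": m.grade if m.grade is not None else "NA",
                "tnm_stage": m.tnm_stage or "NA",
                "ki67_class": m.ki67_class or "NA",
                "intrinsic_subtype": m.intrinsic_subtype or "NA",
                "tils_percent": m.tils_percent if m.tils_percent is not None else "NA",
                "germline_variants": ";".join("|".join(gv) for gv in m.germline_variants)
                or "NA",
            }
        )
    _write_tsv(pd.DataFrame(rows, columns=META_COLUMNS), path, comments)


# ---------------------------------------------------------------------------
# panel definition
# ---------------------------------------------------------------------------


def _read_gene_list(path: str | Path) -> frozenset[str]:
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return frozenset(genes)


def read_panel(
    gene_list_path: str | Path,
    cnv_gene_list_path: str | Path,
    bed_path: str | Path | None = None,
    target_size_mb: float = 1.94,
    msi_locus_count: int = 125,
) -> PanelDefinition:
    """Assemble a panel definition from a gene list, CNV gene list and
    (optionally) a target BED whose total span overrides ``target_size_mb``."""
    genes = _read_gene_list(gene_list_path)
    cnv_genes = _read_gene_list(cnv_gene_list_path)
    if bed_path is not None:
        bed = pd.read_csv(
            bed_path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
        )
        target_size_mb = float((bed["end"] - bed["start"]).sum()) / 1e6
    return PanelDefinition(
        gene_list=genes,
        cnv_gene_list=cnv_genes,
        target_size_mb=target_size_mb,
        msi_locus_count=msi_locus_count,
    )


def write_panel(
    panel: PanelDefinition,
    gene_list_path: str | Path,
    cnv_gene_list_path: str | Path,
) -> None:
    for genes, path in (
        (panel.gene_list, gene_list_path),
        (panel.cnv_gene_list, cnv_gene_list_path),
    ):
        with open(path, "w") as fh:
            for g in sorted(genes):
                fh.write(g + "\n")
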