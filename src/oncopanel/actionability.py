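"""Clinical actionability annotation against a bundled knowledge base.

The knowledge base is a static, versioned snapshot (OncoKB-style) shipped
with the package and user-replaceable: hotspot variant entries (gene +
protein change -> therapy), germline-gene entries (BRCA1/BRCA2/PALB2 ->
PARP inhibitor) and biomarker entries (TMB-high, MSI-high -> immune
checkpoint inhibitor). Germline findings count with or without biallelic
loss; the LOH status is carried in the finding's trigger text.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

from .hgvs import normalize_protein_change
from .io_model import SchemaError

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import SampleProfile

__all__ = [
    "KnowledgeBaseEntry",
    "ActionableFinding",
    "load_kb",
    "default_kb",
    "annotate_sample",
]

_KINDS = frozenset({"variant_hotspot", "germline_gene", "tmb_high", "msi_high"})


@dataclass(frozen=True)
class KnowledgeBaseEntry:
    alteration_kind: str
    gene: str | None
    protein_change: str | None  # stored normalized
    therapy: str
    evidence_note: str

    def __post_init__(self) -> None:
        if self.alteration_kind not in _KINDS:
            raise ValueError(f"unknown alteration_kind {self.alteration_kind!r}")
        if self.alteration_kind == "variant_hotspot":
            if not self.gene or not self.protein_change:
                raise ValueError("variant_hotspot entries need gene + protein_change")
        elif self.alteration_kind == "germline_gene":
            if not self.gene:
                raise ValueError("germline_gene entries need a gene")
        elif self.gene or self.protein_change:
            raise ValueError(
                f"{self.alteration_kind} entries carry neither gene nor protein_change"
            )


@dataclass(frozen=True)
class ActionableFinding:
    sample_id: str
    matched_entry: KnowledgeBaseEntry
    trigger: str


def load_kb(path: str | Path) -> list[KnowledgeBaseEntry]:
    """Load and validate a knowledge-base snapshot TSV.

    Lines starting with ``#`` are version/comment headers. Schema violations
    and duplicated entries are load-time errors with line context.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = ["alteration_kind", "gene", "protein_change", "therapy", "evidence_note"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing KB columns {missing}")
    entries: list[KnowledgeBaseEntry] = []
    seen: set[tuple] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        gene = row.gene if row.gene not in ("", "NA") else None
        pchange = row.protein_change if row.protein_change not in ("", "NA") else None
        try:
            entry = KnowledgeBaseEntry(
                alteration_kind=row.alteration_kind,
                gene=gene,
                protein_change=normalize_protein_change(pchange),
                therapy=row.therapy,
                evidence_note=row.evidence_note,
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: row {idx}: {exc}") from None
        key = (entry.alteration_kind, (entry.gene or "").casefold(), entry.protein_change)
        if key in seen:
            raise SchemaError(f"{path}: row {idx}: duplicate KB entry {key}")
        seen.add(key)
        entries.append(entry)
    return entries


def default_kb() -> list[KnowledgeBaseEntry]:
    """The bundled snapshot."""
    ref = resources.files("oncopanel").joinpath("data/kb_snapshot.tsv")
    with resources.as_file(ref) as path:
        return load_kb(path)


def annotate_sample(
    profile: "SampleProfile", kb: list[KnowledgeBaseEntry]
) -> list[ActionableFinding]:
    """Match one sample profile against the knowledge base.

    Findings are emitted deterministically: driver hotspot matches first (in
    driver order), then germline-gene matches, then TMB-high and MSI-high
    biomarkers. Every finding traces to exactly one alteration.
    """
    hotspots = [e for e in kb if e.alteration_kind == "variant_hotspot"]
    germline_entries = {
        e.gene.casefold(): e for e in kb if e.alteration_kind == "germline_gene"
    }
    tmb_entry = next((e for e in kb if e.alteration_kind == "tmb_high"), None)
    msi_entry = next((e for e in kb if e.alteration_kind == "msi_high"), None)

    findings: list[ActionableFinding] = []
    for v in profile.drivers:
        norm = normalize_protein_change(v.hgvs_p)
        for entry in hotspots:
            if (
                v.gene.casefold() == entry.gene.casefold()
                and norm is not None
                and norm == entry.protein_change
            ):
                trigger = f"{v.gene} {v.hgvs_c or ''} {v.hgvs_p}".strip()
                findings.append(ActionableFinding(profile.sample_id, entry, trigger))
                break
    for call in profile.loh_calls:
        entry = germline_entries.get(call.gene.casefold())
        if entry is not None:
            trigger = (
                f"{call.gene} {call.germline_hgvs_p} germline ({call.status})"
            )
            findings.append(ActionableFinding(profile.sample_id, entry, trigger))
    if tmb_entry is not None and profile.tmb is not None and profile.tmb.stratum == "high":
        findings.append(
            ActionableFinding(
                profile.sample_id, tmb_entry, f"TMB {profile.tmb.tmb:.1f} mut/Mb (high)"
            )
        )
    if msi_entry is not None and profile.msi is not None and profile.msi.stratum == "high":
        findings.append(
            ActionableFinding(
                profile.sample_id, msi_entry, f"MSI {profile.msi.msi_percent:.1f}% (high)"
            )
        )
    return findings
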