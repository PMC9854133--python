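"""Cohort aggregation: gene frequencies, biomarker summaries, oncoprint.

Conventions, fixed and documented here:

* a gene counts once per sample toward mutation frequency regardless of how
  many drivers hit it;
* medians use the mean-of-central-pair convention for even counts;
* display percentages are rounded to one decimal, half up;
* percentages over clinical fields use the non-missing denominator;
* the oncoprint cell vocabulary is {missense, truncating, frameshift,
  amplification, germline, none}; multiple alterations in one cell are
  sorted and joined with ";".
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import SampleMeta
from .pipeline import SampleProfile

__all__ = ["CohortSummary", "summarize_cohort", "write_report", "read_report", "round_half_up"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(numerator: int, denominator: int) -> float | None:
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, 1)


_ONCOPRINT_LABEL = {
    "missense": "missense",
    "inframe_indel": "missense",
    "stop_gained": "truncating",
    "splice_site": "truncating",
    "frameshift": "frameshift",
}


@dataclass
class CohortSummary:
    n_samples: int = 0
    #: gene -> {"n_samples_mutated": int, "percent": float}
    gene_variant_freq: dict = field(default_factory=dict)
    #: {"median": float, "min": int, "max": int, "counts": {sample_id: n}}
    variants_per_sample: dict = field(default_factory=dict)
    #: gene -> {"n_gain": int, "n_loss": int, "percent": float, "median_gain_fc": float}
    cnv_gene_freq: dict = field(default_factory=dict)
    tmb_summary: dict = field(default_factory=dict)
    msi_summary: dict = field(default_factory=dict)
    n_actionable: int = 0
    percent_actionable: float | None = None
    germline_summary: dict = field(default_factory=dict)
    #: clinical field -> {value: {"n": int, "percent": float}} over non-missing
    clinical_summary: dict = field(default_factory=dict)
    #: sample_id -> {gene: label}
    oncoprint: dict = field(default_factory=dict)


def _clinical_counts(metas: list[SampleMeta], fieldname: str) -> dict:
    values = [getattr(m, fieldname) for m in metas]
    present = [v for v in values if v is not None]
    out = {}
    for v in sorted(set(present)):
        n = present.count(v)
        out[str(v)] = {"n": n, "percent": _pct(n, len(present))}
    return out


def summarize_cohort(
    profiles: list[SampleProfile], metas: list[SampleMeta]
) -> CohortSummary:
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in profiles")
    meta_by_id = {m.sample_id: m for m in metas}
    if len(meta_by_id) != len(metas):
        raise ValueError("duplicate sample_id in metadata")

    n = len(profiles)
    summary = CohortSummary(n_samples=n)
    if n == 0:
        return summary

    # somatic gene frequencies (gene counted once per sample)
    gene_samples: dict[str, set[str]] = {}
    for p in profiles:
        for v in p.drivers:
            gene_samples.setdefault(v.gene, set()).add(p.sample_id)
    summary.gene_variant_freq = {
        g: {"n_samples_mutated": len(s), "percent": _pct(len(s), n)}
        for g, s in sorted(gene_samples.items())
    }

    counts = {p.sample_id: len(p.drivers) for p in profiles}
    values = list(counts.values())
    summary.variants_per_sample = {
        "median": float(np.median(values)),
        "min": int(min(values)),
        "max": int(max(values)),
        "counts": counts,
    }

    # CNV frequencies (sample counted once per gene per direction)
    cnv_rows: dict[str, dict] = {}
    for p in profiles:
        for c in p.cnv_classes:
            if c.label == "neutral":
                continue
            row = cnv_rows.setdefault(
                c.call.gene, {"gain_samples": set(), "loss_samples": set(), "gain_fcs": []}
            )
            if c.label == "gain":
                row["gain_samples"].add(p.sample_id)
                row["gain_fcs"].append(c.call.fold_change)
            else:
                row["loss_samples"].add(p.sample_id)
    summary.cnv_gene_freq = {
        g: {
            "n_gain": len(r["gain_samples"]),
            "n_loss": len(r["loss_samples"]),
            "percent": _pct(len(r["gain_samples"] | r["loss_samples"]), n),
            "median_gain_fc": float(np.median(r["gain_fcs"])) if r["gain_fcs"] else None,
        }
        for g, r in sorted(cnv_rows.items())
    }

    tmbs = [p.tmb for p in profiles if p.tmb is not None]
    if tmbs:
        vals = [t.tmb for t in tmbs]
        summary.tmb_summary = {
            "median": float(np.median(vals)),
            "min": float(min(vals)),
            "max": float(max(vals)),
            "n_high": sum(t.stratum == "high" for t in tmbs),
        }
    msis = [p.msi for p in profiles if p.msi is not None]
    evaluable = [m for m in msis if m.evaluable]
    if msis:
        vals = [m.msi_percent for m in evaluable]
        summary.msi_summary = {
            "median": float(np.median(vals)) if vals else None,
            "min": float(min(vals)) if vals else None,
            "max": float(max(vals)) if vals else None,
            "n_high": sum(m.stratum == "high" for m in evaluable),
            "n_stable": sum(m.stratum == "stable" for m in evaluable),
            "n_not_evaluable": sum(not m.evaluable for m in msis),
        }

    summary.n_actionable = sum(p.is_actionable for p in profiles)
    summary.percent_actionable = _pct(summary.n_actionable, n)

    carriers = [p for p in profiles if p.loh_calls]
    summary.germline_summary = {
        "n_carriers": len(carriers),
        "percent_carriers": _pct(len(carriers), n),
        "n_with_loh": sum(
            any(c.status == "LOH" for c in p.loh_calls) for p in carriers
        ),
    }

    for fieldname in ("er", "pr", "her2", "ar", "grade", "ki67_class", "intrinsic_subtype"):
        present_metas = [meta_by_id[i] for i in ids if i in meta_by_id]
        counts_f = _clinical_counts(present_metas, fieldname)
        if counts_f:
            summary.clinical_summary[fieldname] = counts_f

    # oncoprint: all samples appear, even alteration-free ones
    oncoprint: dict[str, dict[str, str]] = {}
    for p in profiles:
        cells: dict[str, set[str]] = {}
        for v in p.drivers:
            cells.setdefault(v.gene, set()).add(
                _ONCOPRINT_LABEL.get(v.consequence, "missense")
            )
        for c in p.cnv_classes:
            if c.label == "gain":
                cells.setdefault(c.call.gene, set()).add("amplification")
        for call in p.loh_calls:
            cells.setdefault(call.gene, set()).add("germline")
        oncoprint[p.sample_id] = {g: ";".join(sorted(s)) for g, s in sorted(cells.items())}
    summary.oncoprint = oncoprint
    return summary


# --- report IO --------------------------------------------------------------


def write_report(summary: CohortSummary, out_dir: str | Path) -> None:
    """Write the structured JSON report plus human-readable TSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(dataclasses.asdict(summary), fh, indent=2)

    pd.DataFrame(
        [
            {"gene": g, **vals}
            for g, vals in summary.gene_variant_freq.items()
        ]
    ).to_csv(out / "gene_variant_freq.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene": g, **vals} for g, vals in summary.cnv_gene_freq.items()]
    ).to_csv(out / "cnv_gene_freq.tsv", sep="\t", index=False)

    genes = sorted({g for cells in summary.oncoprint.values() for g in cells})
    samples = list(summary.oncoprint)
    matrix = pd.DataFrame(
        [[summary.oncoprint[s].get(g, "none") for s in samples] for g in genes],
        index=pd.Index(genes, name="gene"),
        columns=samples,
    )
    matrix.to_csv(out / "oncoprint.tsv", sep="\t")


def read_report(path: str | Path) -> CohortSummary:
    """Read ``summary.json`` back into an equal :class:`CohortSummary`."""
    with open(path) as fh:
        return CohortSummary(**json.load(fh))
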