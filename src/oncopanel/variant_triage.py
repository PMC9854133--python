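"""Driver nomination: the pathogenic-somatic-variant filter cascade.

A call is nominated as a driver when all of the following hold:

* caller FILTER is PASS;
* consequence is protein-affecting coding or splice-site (synonymous,
  intronic and other non-coding classes are excluded);
* variant allele fraction lies in the closed window [vaf_min, vaf_max]
  (default [0.05, 0.90] — the upper bound excludes likely germline calls
  in tumor-only data);
* total read depth >= depth_min (default 40);
* global population allele frequency < popmax_af_max (default 0.01;
  a missing annotation passes by default);
* flagged somatic in the Cancer Gene Census and pathogenic in COSMIC.

Every failing condition is recorded — the audit trail lists all reasons, not
just the first.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_model import AnnotatedVariant, ThresholdConfig, chrom_sort_key

__all__ = [
    "DRIVER_CONSEQUENCES",
    "REJECTION_REASONS",
    "TriageResult",
    "classify_variant",
    "triage_sample",
]

#: Consequence classes eligible for driver nomination.
DRIVER_CONSEQUENCES = frozenset(
    {"missense", "stop_gained", "frameshift", "inframe_indel", "splice_site"}
)

#: Canonical order of rejection reasons in the audit trail.
REJECTION_REASONS = (
    "not_pass",
    "excluded_consequence",
    "vaf_out_of_range",
    "low_depth",
    "common_in_population",
    "not_cgc_somatic",
    "not_cosmic_pathogenic",
)


@dataclass(frozen=True)
class TriageResult:
    variant: AnnotatedVariant
    verdict: str  # "driver" | "rejected"
    rejection_reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.verdict == "driver") != (not self.rejection_reasons):
            raise ValueError("verdict inconsistent with rejection_reasons")


def classify_variant(v: AnnotatedVariant, cfg: ThresholdConfig) -> TriageResult:
    """Evaluate the full filter cascade on one variant (no short-circuit)."""
    reasons = []
    if v.filter_status != "PASS":
        reasons.append("not_pass")
    if v.consequence not in DRIVER_CONSEQUENCES:
        reasons.append("excluded_consequence")
    if not (cfg.vaf_min <= v.vaf <= cfg.vaf_max):
        reasons.append("vaf_out_of_range")
    if v.depth < cfg.depth_min:
        reasons.append("low_depth")
    if v.popmax_af is None:
        if not cfg.popmax_missing_passes:
            reasons.append("common_in_population")
    elif not v.popmax_af < cfg.popmax_af_max:
        reasons.append("common_in_population")
    if not v.cgc_somatic:
        reasons.append("not_cgc_somatic")
    if not v.cosmic_pathogenic:
        reasons.append("not_cosmic_pathogenic")
    verdict = "driver" if not reasons else "rejected"
    return TriageResult(variant=v, verdict=verdict, rejection_reasons=tuple(reasons))


def _genomic_key(v: AnnotatedVariant):
    return (chrom_sort_key(v.chrom), v.pos, v.ref, v.alt)


def triage_sample(
    variants: list[AnnotatedVariant], cfg: ThresholdConfig
) -> tuple[list[AnnotatedVariant], list[TriageResult]]:
    """Triage all calls of one sample.

    Returns the driver list and a full audit, both in genomic order so the
    result is independent of input order. Mixed sample_ids are an error.
    """
    ids = {v.sample_id for v in variants}
    if len(ids) > 1:
        raise ValueError(f"triage_sample got mixed sample_ids: {sorted(ids)}")
    audit = [classify_variant(v, cfg) for v in sorted(variants, key=_genomic_key)]
    drivers = [r.variant for r in audit if r.verdict == "driver"]
    return drivers, audit
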