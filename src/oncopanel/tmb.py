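"""Tumor mutational burden from panel variant calls.

TMB is the count of eligible somatic coding variants divided by the
megabases of targeted genome. The eligibility rule follows the convention
of large hybrid-capture assays: PASS coding variants — including synonymous
— above the VAF floor and depth gate and below the population-frequency
cap, excluding known database hotspots (they are ascertainment-biased on
cancer panels) and known germline variants. Each exclusion is a config
toggle. Samples at or above 10 mut/Mb are stratified TMB-high.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_model import AnnotatedVariant, PanelDefinition, ThresholdConfig

__all__ = ["TMB_CONSEQUENCES", "TmbResult", "select_tmb_eligible", "compute_tmb"]

#: Coding consequence classes counted toward TMB.
TMB_CONSEQUENCES = frozenset(
    {"missense", "synonymous", "stop_gained", "frameshift", "inframe_indel"}
)


@dataclass(frozen=True)
class TmbResult:
    sample_id: str
    eligible_count: int
    panel_mb: float
    tmb: float
    stratum: str  # "high" | "low"


def select_tmb_eligible(
    variants: list[AnnotatedVariant], cfg: ThresholdConfig
) -> list[AnnotatedVariant]:
    """Variants counted toward TMB for one sample."""
    eligible = []
    for v in variants:
        if v.filter_status != "PASS":
            continue
        if v.consequence not in TMB_CONSEQUENCES:
            continue
        if v.consequence == "synonymous" and not cfg.tmb_include_synonymous:
            continue
        if v.vaf < cfg.vaf_min or v.depth < cfg.depth_min:
            continue
        if v.popmax_af is None:
            if not cfg.popmax_missing_passes:
                continue
        elif not v.popmax_af < cfg.popmax_af_max:
            continue
        if cfg.tmb_exclude_hotspots and v.cosmic_pathogenic:
            continue
        if cfg.tmb_exclude_germline and v.origin == "known_germline":
            continue
        eligible.append(v)
    return eligible


def compute_tmb(
    variants: list[AnnotatedVariant],
    panel: PanelDefinition,
    cfg: ThresholdConfig,
    sample_id: str | None = None,
    callable_mb: float | None = None,
) -> TmbResult:
    """TMB in mutations per megabase with high/low stratification.

    ``callable_mb`` overrides the panel target size when a per-sample
    callable-region estimate is available.
    """
    if sample_id is None:
        sample_id = variants[0].sample_id if variants else "sample"
    eligible = select_tmb_eligible(variants, cfg)
    mb = callable_mb if callable_mb is not None else panel.target_size_mb
    if mb <= 0:
        raise ValueError("panel megabases must be > 0")
    tmb = len(eligible) / mb
    stratum = "high" if tmb >= cfg.tmb_high_cutoff else "low"
    return TmbResult(
        sample_id=sample_id,
        eligible_count=len(eligible),
        panel_mb=mb,
        tmb=tmb,
        stratum=stratum,
    )
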