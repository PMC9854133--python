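"""Loss-of-heterozygosity evaluation at known germline pathogenic variants.

For each germline variant declared in a sample's metadata, the matching call
is looked up in the raw tumor call set (by gene plus normalized HGVS) and the
tumor allele fraction is compared against the LOH threshold: a germline
heterozygous variant whose tumor VAF exceeds 50% indicates loss of the
wild-type allele. Matching uses the raw calls, not the triaged driver set,
because germline variants legitimately exceed the somatic VAF ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hgvs import normalize_protein_change
from .io_model import AnnotatedVariant, SampleMeta, ThresholdConfig

__all__ = ["LohCall", "evaluate_loh"]


@dataclass(frozen=True)
class LohCall:
    sample_id: str
    gene: str
    germline_hgvs_c: str
    germline_hgvs_p: str
    tumor_vaf: float | None
    status: str  # "LOH" | "NO_LOH" | "NOT_EVALUABLE"


def _matches(
    variant: AnnotatedVariant, gene: str, hgvs_c: str, hgvs_p: str
) -> bool:
    if variant.gene.casefold() != gene.casefold():
        return False
    norm_p = normalize_protein_change(hgvs_p)
    if norm_p is not None and normalize_protein_change(variant.hgvs_p) == norm_p:
        return True
    return bool(hgvs_c) and variant.hgvs_c == hgvs_c


def evaluate_loh(
    meta: SampleMeta,
    tumor_variants: list[AnnotatedVariant],
    cfg: ThresholdConfig,
) -> list[LohCall]:
    """One :class:`LohCall` per declared germline variant.

    Status is LOH iff the matched tumor VAF is strictly greater than
    ``cfg.loh_vaf``; a germline variant absent from the tumor call set is
    NOT_EVALUABLE.
    """
    calls = []
    for gene, hgvs_c, hgvs_p in meta.germline_variants:
        match = next(
            (v for v in tumor_variants if _matches(v, gene, hgvs_c, hgvs_p)), None
        )
        if match is None:
            status, vaf = "NOT_EVALUABLE", None
        else:
            vaf = match.vaf
            status = "LOH" if vaf > cfg.loh_vaf else "NO_LOH"
        calls.append(
            LohCall(
                sample_id=meta.sample_id,
                gene=gene,
                germline_hgvs_c=hgvs_c,
                germline_hgvs_p=hgvs_p,
                tumor_vaf=vaf,
                status=status,
            )
        )
    return calls
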