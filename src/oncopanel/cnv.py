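"""Copy-number classification from gene-level fold-changes.

Fold-changes come from the upstream CNV caller (1.0 = diploid). A gene is a
gain at fold-change >= 1.5 (about three copies), a loss at <= 0.5 (one
copy), neutral in between. The integer copy estimate is
round(2 x fold-change), rounding half away from zero so 1.5 maps to three
copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .io_model import CnvCall, PanelDefinition, ThresholdConfig

__all__ = ["CnvClass", "classify_cnv", "summarize_cnv"]


@dataclass(frozen=True)
class CnvClass:
    call: CnvCall
    label: str  # "gain" | "loss" | "neutral"
    estimated_copies: int


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def classify_cnv(
    call: CnvCall, cfg: ThresholdConfig, panel: PanelDefinition | None = None
) -> CnvClass:
    """Assign exactly one of gain/loss/neutral and an integer copy estimate.

    If a panel is supplied, a gene outside its CNV-eligible subset raises
    ValueError (the caller only reports fold-changes for that subset).
    """
    if panel is not None and call.gene not in panel.cnv_gene_list:
        raise ValueError(
            f"gene {call.gene} is not eligible for CNV calling on this panel"
        )
    fc = call.fold_change
    if fc >= cfg.cnv_gain_fc:
        label = "gain"
    elif fc <= cfg.cnv_loss_fc:
        label = "loss"
    else:
        label = "neutral"
    return CnvClass(call=call, label=label, estimated_copies=_round_half_away(2 * fc))


def summarize_cnv(calls: list[CnvCall], cfg: ThresholdConfig) -> pd.DataFrame:
    """Per-gene gain/loss counts with the median fold-change among gains.

    Genes with neither gains nor losses are omitted. The median follows the
    mean-of-central-pair convention for even counts (numpy default).
    """
    classes = [classify_cnv(c, cfg) for c in calls]
    rows = []
    genes = sorted({c.call.gene for c in classes})
    for gene in genes:
        gene_classes = [c for c in classes if c.call.gene == gene]
        gains = [c.call.fold_change for c in gene_classes if c.label == "gain"]
        losses = [c for c in gene_classes if c.label == "loss"]
        if not gains and not losses:
            continue
        rows.append(
            {
                "gene": gene,
                "n_gain": len(gains),
                "n_loss": len(losses),
                "median_gain_fc": float(pd.Series(gains).median()) if gains else None,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "n_gain", "n_loss", "median_gain_fc"])
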