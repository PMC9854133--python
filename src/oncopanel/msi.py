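"""Microsatellite instability from homopolymer read-length histograms.

Each of the panel's homopolymer loci is assessed when its coverage reaches
the 60-read gate. The default per-locus test calls a locus unstable when
the observed fraction of reads at non-reference repeat lengths exceeds the
baseline (stutter-only) expectation by more than a fixed margin; a
Jensen-Shannon distance test against the baseline profile is available
behind the same interface (``msi_method: js``). The sample-level MSI value
is the percentage of unstable sites among assessed sites: >= 10% is
MSI-high, zero unstable sites is stable, and a sample with no assessable
loci is not evaluable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon

from .io_model import MsiLocusObservation, ThresholdConfig

__all__ = ["LocusAssessment", "MsiResult", "assess_locus", "compute_msi"]


@dataclass(frozen=True)
class LocusAssessment:
    locus_id: str
    coverage: int
    assessed: bool
    unstable: bool
    shift_fraction: float


@dataclass(frozen=True)
class MsiResult:
    sample_id: str
    n_assessed: int
    n_unstable: int
    msi_percent: float | None
    stratum: str  # "high" | "low" | "stable" | "not_evaluable"

    @property
    def evaluable(self) -> bool:
        return self.stratum != "not_evaluable"


def _off_reference_fraction(hist: dict[int, float], ref_len: int) -> float:
    total = sum(hist.values())
    if total == 0:
        return 0.0
    return sum(v for k, v in hist.items() if k != ref_len) / total


def _js_distance(obs: MsiLocusObservation) -> float:
    lengths = sorted(set(obs.read_length_histogram) | set(obs.baseline_histogram))
    p = np.array([obs.read_length_histogram.get(l, 0) for l in lengths], dtype=float)
    q = np.array([obs.baseline_histogram.get(l, 0.0) for l in lengths], dtype=float)
    if p.sum() == 0:
        return 0.0
    return float(jensenshannon(p / p.sum(), q, base=2))


def assess_locus(obs: MsiLocusObservation, cfg: ThresholdConfig) -> LocusAssessment:
    """Coverage-gated per-locus stability call.

    ``shift_fraction`` is the excess of the observed off-reference read
    fraction over the baseline off-reference proportion (floored at 0); under
    the JS method it is the Jensen-Shannon distance instead. A locus below
    the coverage gate is never unstable.
    """
    coverage = obs.coverage
    assessed = coverage >= cfg.msi_min_coverage
    ref = obs.reference_repeat_length
    if cfg.msi_method == "js":
        shift = _js_distance(obs)
    else:
        observed = _off_reference_fraction(dict(obs.read_length_histogram), ref)
        expected = sum(
            v for k, v in obs.baseline_histogram.items() if k != ref
        )
        shift = max(0.0, observed - expected)
    unstable = assessed and shift > cfg.locus_instability_threshold
    return LocusAssessment(
        locus_id=obs.locus_id,
        coverage=coverage,
        assessed=assessed,
        unstable=unstable,
        shift_fraction=shift,
    )


def compute_msi(
    loci: list[LocusAssessment], cfg: ThresholdConfig, sample_id: str = "sample"
) -> MsiResult:
    """Sample-level MSI percentage and stratum from per-locus assessments."""
    assessed = [l for l in loci if l.assessed]
    n_assessed = len(assessed)
    n_unstable = sum(l.unstable for l in assessed)
    if n_assessed == 0:
        return MsiResult(sample_id, 0, 0, None, "not_evaluable")
    pct = 100.0 * n_unstable / n_assessed
    if n_unstable == 0:
        stratum = "stable"
    elif pct >= cfg.msi_high_pct:
        stratum = "high"
    else:
        stratum = "low"
    return MsiResult(sample_id, n_assessed, n_unstable, pct, stratum)
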