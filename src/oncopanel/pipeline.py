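"""Per-sample orchestration: assemble a full molecular profile.

A :class:`SampleProfile` bundles everything the downstream report needs:
triaged drivers with the full audit, LOH calls at germline variants, CNV
classes, TMB, MSI and actionable findings. Profiles serialize to JSON and
round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .actionability import ActionableFinding, KnowledgeBaseEntry, annotate_sample
from .cnv import CnvClass, classify_cnv
from .io_model import (
    AnnotatedVariant,
    CnvCall,
    MsiLocusObservation,
    PanelDefinition,
    SampleMeta,
    ThresholdConfig,
)
from .loh import LohCall, evaluate_loh
from .msi import MsiResult, assess_locus, compute_msi
from .tmb import TmbResult, compute_tmb
from .variant_triage import TriageResult, triage_sample

__all__ = ["SampleProfile", "build_sample_profile", "write_profile", "read_profile"]


@dataclass
class SampleProfile:
    sample_id: str
    drivers: list[AnnotatedVariant] = field(default_factory=list)
    triage_audit: list[TriageResult] = field(default_factory=list)
    loh_calls: list[LohCall] = field(default_factory=list)
    cnv_classes: list[CnvClass] = field(default_factory=list)
    tmb: TmbResult | None = None
    msi: MsiResult | None = None
    actionable: list[ActionableFinding] = field(default_factory=list)

    @property
    def is_actionable(self) -> bool:
        return bool(self.actionable)


def build_sample_profile(
    sample_id: str,
    variants: list[AnnotatedVariant],
    cnv_calls: list[CnvCall],
    msi_observations: list[MsiLocusObservation],
    meta: SampleMeta,
    panel: PanelDefinition,
    cfg: ThresholdConfig,
    kb: list[KnowledgeBaseEntry] | None = None,
) -> SampleProfile:
    """Run every profiling stage for one sample."""
    drivers, audit = triage_sample(variants, cfg)
    loh_calls = evaluate_loh(meta, variants, cfg)
    cnv_classes = [classify_cnv(c, cfg, panel) for c in cnv_calls]
    tmb = compute_tmb(variants, panel, cfg, sample_id=sample_id)
    assessments = [assess_locus(o, cfg) for o in msi_observations]
    msi = compute_msi(assessments, cfg, sample_id=sample_id)
    profile = SampleProfile(
        sample_id=sample_id,
        drivers=drivers,
        triage_audit=audit,
        loh_calls=loh_calls,
        cnv_classes=cnv_classes,
        tmb=tmb,
        msi=msi,
    )
    if kb is not None:
        profile.actionable = annotate_sample(profile, kb)
    return profile


# --- JSON serialization -----------------------------------------------------


def profile_to_dict(profile: SampleProfile) -> dict:
    return {
        "sample_id": profile.sample_id,
        "drivers": [dataclasses.asdict(v) for v in profile.drivers],
        "triage_audit": [
            {
                "variant": dataclasses.asdict(r.variant),
                "verdict": r.verdict,
                "rejection_reasons": list(r.rejection_reasons),
            }
            for r in profile.triage_audit
        ],
        "loh_calls": [dataclasses.asdict(c) for c in profile.loh_calls],
        "cnv_classes": [
            {
                "call": dataclasses.asdict(c.call),
                "label": c.label,
                "estimated_copies": c.estimated_copies,
            }
            for c in profile.cnv_classes
        ],
        "tmb": dataclasses.asdict(profile.tmb) if profile.tmb else None,
        "msi": dataclasses.asdict(profile.msi) if profile.msi else None,
        "actionable": [
            {
                "matched_entry": dataclasses.asdict(f.matched_entry),
                "trigger": f.trigger,
            }
            for f in profile.actionable
        ],
    }


def _variant_from_dict(d: dict) -> AnnotatedVariant:
    return AnnotatedVariant(**d)


def profile_from_dict(d: dict) -> SampleProfile:
    from .cnv import CnvClass  # local to keep imports tidy
    from .msi import MsiResult
    from .tmb import TmbResult
    from .variant_triage import TriageResult

    sample_id = d["sample_id"]
    return SampleProfile(
        sample_id=sample_id,
        drivers=[_variant_from_dict(v) for v in d["drivers"]],
        triage_audit=[
            TriageResult(
                variant=_variant_from_dict(r["variant"]),
                verdict=r["verdict"],
                rejection_reasons=tuple(r["rejection_reasons"]),
            )
            for r in d.get("triage_audit", [])
        ],
        loh_calls=[LohCall(**c) for c in d.get("loh_calls", [])],
        cnv_classes=[
            CnvClass(
                call=CnvCall(**c["call"]),
                label=c["label"],
                estimated_copies=c["estimated_copies"],
            )
            for c in d.get("cnv_classes", [])
        ],
        tmb=TmbResult(**d["tmb"]) if d.get("tmb") else None,
        msi=MsiResult(**d["msi"]) if d.get("msi") else None,
        actionable=[
            ActionableFinding(
                sample_id=sample_id,
                matched_entry=KnowledgeBaseEntry(**f["matched_entry"]),
                trigger=f["trigger"],
            )
            for f in d.get("actionable", [])
        ],
    )


def write_profile(profile: SampleProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(profile_to_dict(profile), fh, indent=2)


def read_profile(path: str | Path) -> SampleProfile:
    with open(path) as fh:
        return profile_from_dict(json.load(fh))
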