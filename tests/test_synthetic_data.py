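"""Simulator contracts: determinism, truth recovery, distributional sanity."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from oncopanel import (
    SimulationConfig,
    compute_msi,
    assess_locus,
    default_panel,
    read_cnv_table,
    read_msi_table,
    read_sample_meta,
    read_variants,
    simulate_cohort,
    triage_sample,
    write_cohort,
)


def _tree_digest(d):
    h = hashlib.sha256()
    for p in sorted(Path(d).rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def test_default_panel_dimensions():
    panel = default_panel()
    assert len(panel.gene_list) == 523
    assert len(panel.cnv_gene_list) == 59
    assert panel.target_size_mb == 1.94
    assert panel.msi_locus_count == 125


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    for sub in ("a", "b"):
        write_cohort(simulate_cohort(SimulationConfig(seed=42)), tmp_path / sub)
    assert _tree_digest(tmp_path / "a") == _tree_digest(tmp_path / "b")


def test_different_seeds_differ(tmp_path):
    for seed in (1, 2):
        write_cohort(simulate_cohort(SimulationConfig(seed=seed)), tmp_path / str(seed))
    assert _tree_digest(tmp_path / "1") != _tree_digest(tmp_path / "2")


def test_outputs_parse_cleanly_through_io_model(tmp_path):
    sim = simulate_cohort(SimulationConfig(seed=3, n_samples=4))
    write_cohort(sim, tmp_path)
    for sid in sim.sample_ids:
        back = read_variants(tmp_path / f"{sid}.vcf", sid)
        assert sorted(back, key=lambda v: v.key) == sorted(
            sim.variants[sid], key=lambda v: v.key
        )
    assert read_cnv_table(tmp_path / "cnv.tsv") == [
        c for sid in sim.sample_ids for c in sim.cnv_calls[sid]
    ]
    assert read_msi_table(tmp_path / "msi.tsv") == [
        o for sid in sim.sample_ids for o in sim.msi_observations[sid]
    ]
    assert read_sample_meta(tmp_path / "meta.tsv") == sim.metas


def test_zero_artifacts_fixed_drivers_recovered_exactly(cfg):
    sim = simulate_cohort(
        SimulationConfig(seed=9, artifact_rate=0.0, drivers_min=3, drivers_max=3)
    )
    for sid in sim.sample_ids:
        drivers, _ = triage_sample(sim.variants[sid], cfg)
        assert len(drivers) == 3
        assert {v.key for v in drivers} == set(sim.truth.drivers[sid])


def test_no_msi_high_fraction_gives_only_stable_or_low(cfg):
    sim = simulate_cohort(SimulationConfig(seed=17, msi_high_fraction=0.0))
    for sid in sim.sample_ids:
        res = compute_msi(
            [assess_locus(o, cfg) for o in sim.msi_observations[sid]], cfg, sid
        )
        assert res.stratum in {"stable", "low"}


def test_artifacts_sit_below_vaf_floor_and_are_deamination_like(cfg):
    sim = simulate_cohort(SimulationConfig(seed=23, artifact_rate=10.0))
    artifact_keys = {
        (sid, k) for sid in sim.sample_ids for k in sim.truth.artifacts[sid]
    }
    seen = 0
    for sid in sim.sample_ids:
        for v in sim.variants[sid]:
            if (sid, v.key) in artifact_keys:
                seen += 1
                assert v.vaf < cfg.vaf_min
                assert (v.ref, v.alt) in {("C", "T"), ("G", "A")}
    assert seen == len(artifact_keys) > 0


def test_driver_vaf_mean_tracks_cellularity():
    """Empirical driver VAF mean within 3 SE of cellularity/2 midpoint."""
    cfg_sim = SimulationConfig(seed=31, n_samples=40, drivers_min=3, drivers_max=5)
    sim = simulate_cohort(cfg_sim)
    keys = {(sid, k) for sid in sim.sample_ids for k in sim.truth.drivers[sid]}
    vafs = [
        v.vaf
        for sid in sim.sample_ids
        for v in sim.variants[sid]
        if (sid, v.key) in keys
    ]
    lo, hi = cfg_sim.cellularity_range
    expected = (lo + hi) / 2 / 2
    # VAF spread: cellularity uniform + per-variant noise
    width = (hi - lo) / 2 / np.sqrt(12)
    se = np.sqrt(width**2 + cfg_sim.driver_vaf_sd**2) / np.sqrt(len(vafs))
    assert abs(np.mean(vafs) - expected) < 3 * se + 0.02


def test_invalid_config_rejected_before_generation():
    with pytest.raises(ValueError):
        SimulationConfig(n_samples=0)
    with pytest.raises(ValueError):
        SimulationConfig(msi_high_fraction=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(drivers_min=4, drivers_max=2)


def test_fixture_determinism(tmp_path, fixture_cohort):
    from oncopanel import emit_paper_fixture

    emit_paper_fixture(tmp_path / "a")
    emit_paper_fixture(tmp_path / "b")
    assert _tree_digest(tmp_path / "a") == _tree_digest(tmp_path / "b")
    assert len(fixture_cohort.sample_ids) == 15


def test_fixture_encodes_printed_strata(fixture_cohort):
    t = fixture_cohort.truth
    assert t.msi_stratum["MBC01"] == "not_evaluable"
    assert t.tmb_stratum["MBC01"] == "high"
    assert t.msi_stratum["MBC02"] == "high"
    assert t.tmb_stratum["MBC03"] == "high"
    assert t.msi_stratum["MBC08"] == "high"
    assert [g["loh"] for s in ("MBC01", "MBC04", "MBC05", "MBC12")
            for g in t.germline[s]] == [True, False, True, False]
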