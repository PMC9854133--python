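"""TMB eligibility, arithmetic and stratification."""

import dataclasses

import pytest

from oncopanel import ThresholdConfig, compute_tmb, default_panel, select_tmb_eligible

from conftest import make_variant


def eligible_variant(**overrides):
    base = dict(
        consequence="synonymous", vaf=0.20, depth=200, popmax_af=0.0,
        cgc_somatic=False, cosmic_pathogenic=False,
    )
    base.update(overrides)
    return make_variant(**base)


def test_synonymous_pass_variant_is_eligible(cfg):
    assert select_tmb_eligible([eligible_variant()], cfg) != []


@pytest.mark.parametrize(
    "overrides",
    [
        dict(cosmic_pathogenic=True),          # database hotspot
        dict(origin="known_germline"),
        dict(filter_status="q30"),
        dict(consequence="intronic"),
        dict(vaf=0.04),
        dict(depth=30),
        dict(popmax_af=0.05),
    ],
)
def test_ineligible_classes_excluded(cfg, overrides):
    assert select_tmb_eligible([eligible_variant(**overrides)], cfg) == []


def test_exclusions_are_toggleable():
    hotspot = eligible_variant(cosmic_pathogenic=True)
    keep_hotspots = ThresholdConfig(tmb_exclude_hotspots=False)
    assert select_tmb_eligible([hotspot], keep_hotspots) == [hotspot]
    no_syn = ThresholdConfig(tmb_include_synonymous=False)
    assert select_tmb_eligible([eligible_variant()], no_syn) == []


def test_24_eligible_on_default_panel_is_high(cfg):
    panel = default_panel()
    variants = [eligible_variant(pos=1000 + i) for i in range(24)]
    res = compute_tmb(variants, panel, cfg, sample_id="s1")
    assert res.eligible_count == 24
    assert res.tmb == pytest.approx(24 / 1.94)
    assert res.tmb == pytest.approx(12.371134, abs=1e-6)
    assert res.stratum == "high"


def test_zero_eligible_is_low(cfg):
    res = compute_tmb([], default_panel(), cfg, sample_id="s1")
    assert (res.eligible_count, res.tmb, res.stratum) == (0, 0.0, "low")


def test_cutoff_boundary_is_high(cfg):
    # 10.0 mut/Mb exactly: callable-region override makes the boundary exact
    variants = [eligible_variant(pos=1000 + i) for i in range(20)]
    res = compute_tmb(variants, default_panel(), cfg, sample_id="s1", callable_mb=2.0)
    assert res.tmb == 10.0
    assert res.stratum == "high"


def test_tmb_linear_in_count_and_inverse_in_panel_size(cfg):
    panel = default_panel()
    for n in (1, 5, 10):
        variants = [eligible_variant(pos=1000 + i) for i in range(n)]
        assert compute_tmb(variants, panel, cfg).tmb == pytest.approx(n / 1.94)
        assert compute_tmb(variants, panel, cfg, callable_mb=3.88).tmb == pytest.approx(
            n / 3.88
        )


def test_adding_non_eligible_variant_never_changes_tmb(cfg):
    panel = default_panel()
    variants = [eligible_variant(pos=1000 + i) for i in range(5)]
    base = compute_tmb(variants, panel, cfg).tmb
    noisy = variants + [
        eligible_variant(pos=1, cosmic_pathogenic=True),
        eligible_variant(pos=2, vaf=0.01),
        eligible_variant(pos=3, origin="known_germline"),
    ]
    assert compute_tmb(noisy, panel, cfg).tmb == base


def test_fixture_cohort_has_two_tmb_high_samples(fixture_profiles):
    high = [p.sample_id for p in fixture_profiles if p.tmb.stratum == "high"]
    assert high == ["MBC01", "MBC03"]
    by_id = {p.sample_id: p.tmb for p in fixture_profiles}
    assert by_id["MBC01"].tmb > 10 and by_id["MBC03"].tmb > 10


def test_simulated_eligible_counts_recovered_exactly(cfg):
    from oncopanel import SimulationConfig, simulate_cohort

    sim = simulate_cohort(SimulationConfig(seed=5))
    for sid in sim.sample_ids:
        res = compute_tmb(sim.variants[sid], sim.panel, cfg, sample_id=sid)
        assert res.eligible_count == sim.truth.tmb_eligible_count[sid]
        assert res.stratum == sim.truth.tmb_stratum[sid]
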