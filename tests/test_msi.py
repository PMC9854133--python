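"""Per-locus instability test and sample-level MSI stratification."""

import random

import pytest

from oncopanel import MsiLocusObservation, ThresholdConfig, assess_locus, compute_msi


def locus(counts, baseline=None, ref_len=12, locus_id="L001"):
    if baseline is None:
        baseline = {11: 0.0375, 12: 0.95, 13: 0.0125}
    return MsiLocusObservation("s1", locus_id, ref_len, counts, baseline)


def stable_assessment(cfg, locus_id="L001", coverage=100):
    return assess_locus(
        locus({11: round(0.0375 * coverage), 12: coverage - round(0.05 * coverage),
               13: round(0.0125 * coverage)}, locus_id=locus_id),
        cfg,
    )


def unstable_assessment(cfg, locus_id="L001"):
    return assess_locus(locus({9: 20, 10: 20, 12: 55, 11: 5}), cfg)


def test_coverage_below_gate_never_assessed(cfg):
    a = assess_locus(locus({12: 59}), cfg)
    assert (a.assessed, a.unstable) == (False, False)
    assert a.coverage == 59


def test_histogram_matching_baseline_is_stable(cfg):
    # pure stutter: observed proportions equal the baseline exactly
    a = assess_locus(locus({11: 5, 12: 90, 13: 5}, baseline={11: 0.05, 12: 0.9, 13: 0.05}), cfg)
    assert a.assessed and not a.unstable
    assert a.shift_fraction == pytest.approx(0.0)


def test_excess_shift_beyond_threshold_is_unstable(cfg):
    # baseline off-reference 0.05, observed 40/100 off-reference
    a = assess_locus(
        locus({10: 30, 11: 10, 12: 60}, baseline={11: 0.05, 12: 0.95}), cfg
    )
    assert a.shift_fraction == pytest.approx(0.35)
    assert a.unstable


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        locus({12: -5})


def test_js_method_agrees_on_clear_cases():
    cfg_js = ThresholdConfig(msi_method="js")
    assert not stable_assessment(cfg_js).unstable
    assert unstable_assessment(cfg_js).unstable


def test_msi_percent_and_high_stratum(cfg):
    loci = [unstable_assessment(cfg, f"L{i:03d}") for i in range(22)] + [
        stable_assessment(cfg, f"L{i:03d}") for i in range(22, 125)
    ]
    res = compute_msi(loci, cfg, "s1")
    assert (res.n_assessed, res.n_unstable) == (125, 22)
    assert res.msi_percent == pytest.approx(17.6)
    assert res.stratum == "high"


def test_no_unstable_sites_is_stable(cfg):
    res = compute_msi([stable_assessment(cfg, f"L{i}") for i in range(125)], cfg)
    assert res.msi_percent == 0.0
    assert res.stratum == "stable"


def test_low_stratum_arithmetic(cfg):
    loci = [unstable_assessment(cfg, f"L{i}") for i in range(3)] + [
        stable_assessment(cfg, f"L{i}") for i in range(3, 120)
    ]
    res = compute_msi(loci, cfg)
    assert res.msi_percent == pytest.approx(2.5)
    assert res.stratum == "low"


def test_no_assessable_loci_is_not_evaluable(cfg):
    low_cov = assess_locus(locus({12: 10}), cfg)
    res = compute_msi([low_cov], cfg)
    assert res.stratum == "not_evaluable"
    assert not res.evaluable
    assert res.msi_percent is None


def test_percent_invariant_to_order_and_unassessed_loci(cfg):
    loci = [unstable_assessment(cfg, f"L{i}") for i in range(5)] + [
        stable_assessment(cfg, f"L{i}") for i in range(5, 80)
    ]
    shuffled = list(loci)
    random.Random(1).shuffle(shuffled)
    base = compute_msi(loci, cfg)
    assert compute_msi(shuffled, cfg) == base
    with_unassessed = loci + [assess_locus(locus({12: 5}), cfg)]
    assert compute_msi(with_unassessed, cfg).msi_percent == base.msi_percent


def test_strata_partition(cfg):
    """stable, low and high are mutually exclusive and driven by the percent."""
    for n_unstable in (0, 1, 11, 13, 125):
        loci = [unstable_assessment(cfg, f"L{i}") for i in range(n_unstable)] + [
            stable_assessment(cfg, f"L{i}") for i in range(n_unstable, 125)
        ]
        res = compute_msi(loci, cfg)
        pct = 100.0 * n_unstable / 125
        if n_unstable == 0:
            assert res.stratum == "stable"
        elif pct >= cfg.msi_high_pct:
            assert res.stratum == "high"
        else:
            assert res.stratum == "low"


def test_fixture_msi_strata(fixture_profiles):
    by_id = {p.sample_id: p.msi for p in fixture_profiles}
    assert by_id["MBC01"].stratum == "not_evaluable"
    assert by_id["MBC02"].stratum == "high"
    assert by_id["MBC02"].msi_percent == pytest.approx(17.6)
    assert by_id["MBC08"].stratum == "high"
    assert by_id["MBC08"].msi_percent == pytest.approx(100 * 17 / 119)
    assert by_id["MBC06"].stratum == "stable"
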