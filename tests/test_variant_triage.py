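"""Driver filter cascade: examples, brute-force oracle, monotonicity."""

import dataclasses
import random

import pytest

from oncopanel import ThresholdConfig, classify_variant, triage_sample
from oncopanel.variant_triage import DRIVER_CONSEQUENCES

from conftest import make_variant


def brute_force_is_driver(v, cfg):
    """Independent restatement of the predicate, evaluated naively."""
    pop_ok = (
        cfg.popmax_missing_passes if v.popmax_af is None
        else v.popmax_af < cfg.popmax_af_max
    )
    return (
        v.filter_status == "PASS"
        and v.consequence in {"missense", "stop_gained", "frameshift",
                              "inframe_indel", "splice_site"}
        and cfg.vaf_min <= v.vaf <= cfg.vaf_max
        and v.depth >= cfg.depth_min
        and pop_ok
        and v.cgc_somatic
        and v.cosmic_pathogenic
    )


def random_variants(n, seed):
    rng = random.Random(seed)
    out = []
    for i in range(n):
        out.append(
            make_variant(
                chrom=f"chr{rng.randint(1, 22)}",
                pos=rng.randint(1, 10_000_000),
                ref="C",
                alt="T",
                consequence=rng.choice(sorted(
                    DRIVER_CONSEQUENCES | {"synonymous", "intronic", "other"}
                )),
                vaf=round(rng.uniform(0.0, 1.0), 3),
                depth=rng.randint(0, 300),
                popmax_af=rng.choice([None, 0.0, 0.005, 0.01, 0.2]),
                cgc_somatic=rng.random() < 0.7,
                cosmic_pathogenic=rng.random() < 0.7,
                filter_status=rng.choice(["PASS", "PASS", "q30"]),
            )
        )
    return out


def test_pik3ca_hotspot_is_driver(cfg):
    res = classify_variant(make_variant(), cfg)
    assert res.verdict == "driver"
    assert res.rejection_reasons == ()


@pytest.mark.parametrize(
    "overrides, expected_reasons",
    [
        (dict(consequence="synonymous"), ("excluded_consequence",)),
        (dict(consequence="intronic"), ("excluded_consequence",)),
        (dict(vaf=0.95), ("vaf_out_of_range",)),
        (dict(vaf=0.04), ("vaf_out_of_range",)),
        (dict(depth=39), ("low_depth",)),
        (dict(popmax_af=0.01), ("common_in_population",)),
        (dict(filter_status="q30"), ("not_pass",)),
        (dict(cgc_somatic=False), ("not_cgc_somatic",)),
        (dict(cosmic_pathogenic=False), ("not_cosmic_pathogenic",)),
        (dict(vaf=0.02, depth=10, cgc_somatic=False),
         ("vaf_out_of_range", "low_depth", "not_cgc_somatic")),
    ],
)
def test_rejection_reasons_recorded_without_short_circuit(cfg, overrides, expected_reasons):
    res = classify_variant(make_variant(**overrides), cfg)
    assert res.verdict == "rejected"
    assert res.rejection_reasons == expected_reasons


@pytest.mark.parametrize("vaf, expected", [(0.05, "driver"), (0.90, "driver"),
                                           (0.049, "rejected"), (0.901, "rejected")])
def test_vaf_window_is_closed_interval(cfg, vaf, expected):
    assert classify_variant(make_variant(vaf=vaf), cfg).verdict == expected


def test_missing_popmax_passes_by_default_and_is_configurable():
    v = make_variant(popmax_af=None)
    assert classify_variant(v, ThresholdConfig()).verdict == "driver"
    strict = ThresholdConfig(popmax_missing_passes=False)
    assert "common_in_population" in classify_variant(v, strict).rejection_reasons


def test_matches_brute_force_oracle_on_random_variants(cfg):
    variants = random_variants(500, seed=20260927)
    drivers, audit = triage_sample(variants, cfg)
    expected = {v.key for v in variants if brute_force_is_driver(v, cfg)}
    assert {v.key for v in drivers} == expected
    assert len(audit) == len(variants)


def test_monotonic_under_threshold_relaxation():
    variants = random_variants(300, seed=7)
    base = ThresholdConfig()
    n_base = len(triage_sample(variants, base)[0])
    for relaxed in (
        dataclasses.replace(base, vaf_min=0.01),
        dataclasses.replace(base, depth_min=5),
        dataclasses.replace(base, popmax_af_max=0.5),
        dataclasses.replace(base, vaf_max=0.99),
    ):
        assert len(triage_sample(variants, relaxed)[0]) >= n_base


def test_audit_independent_of_input_order(cfg):
    variants = random_variants(100, seed=3)
    shuffled = list(variants)
    random.Random(99).shuffle(shuffled)
    assert triage_sample(variants, cfg) == triage_sample(shuffled, cfg)


def test_drivers_sorted_by_genomic_position(cfg):
    variants = [
        make_variant(chrom="chr10", pos=5),
        make_variant(chrom="chr2", pos=9),
        make_variant(chrom="chr2", pos=3),
    ]
    drivers, _ = triage_sample(variants, cfg)
    assert [(v.chrom, v.pos) for v in drivers] == [("chr2", 3), ("chr2", 9), ("chr10", 5)]


def test_mixed_sample_ids_rejected(cfg):
    with pytest.raises(ValueError, match="mixed sample_ids"):
        triage_sample([make_variant(), make_variant(sample_id="other")], cfg)


def test_empty_input_gives_empty_outputs(cfg):
    assert triage_sample([], cfg) == ([], [])
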