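"""Cohort aggregation, oncoprint conservation, report round trip."""

import pytest

from oncopanel import read_report, summarize_cohort, write_report
from oncopanel.cohort_report import round_half_up


@pytest.fixture(scope="module")
def summary(fixture_profiles, fixture_cohort):
    return summarize_cohort(fixture_profiles, fixture_cohort.metas)


def test_actionable_fraction(summary):
    assert summary.n_actionable == 11
    assert summary.percent_actionable == 73.3


def test_pik3ca_frequency(summary):
    row = summary.gene_variant_freq["PIK3CA"]
    assert row == {"n_samples_mutated": 6, "percent": 40.0}


def test_variants_per_sample_distribution(summary):
    d = summary.variants_per_sample
    assert (d["median"], d["min"], d["max"]) == (2.0, 1, 5)
    assert sum(d["counts"].values()) == 40
    assert sorted(d["counts"].values()).count(5) == 3


def test_germline_summary(summary):
    assert summary.germline_summary == {
        "n_carriers": 4,
        "percent_carriers": 26.7,
        "n_with_loh": 2,
    }


def test_myc_amplification_frequency(summary):
    row = summary.cnv_gene_freq["MYC"]
    assert row["n_gain"] == 8
    assert row["percent"] == 53.3
    assert row["median_gain_fc"] == pytest.approx(1.9)


def test_biomarker_summaries(summary):
    assert summary.tmb_summary["n_high"] == 2
    assert summary.msi_summary["n_high"] == 2
    assert summary.msi_summary["n_not_evaluable"] == 1
    assert summary.msi_summary["median"] == pytest.approx(2.4)
    assert summary.msi_summary["max"] == pytest.approx(17.6)


def test_missing_clinical_fields_use_reduced_denominator(summary):
    # HER2 is missing for one sample: 3 positives of 14 evaluable
    her2 = summary.clinical_summary["her2"]
    assert her2["positive"] == {"n": 3, "percent": 21.4}
    assert her2["negative"]["n"] == 11
    assert her2["negative"]["percent"] == 78.6


def test_oncoprint_covers_all_samples_and_conserves_counts(summary, fixture_profiles):
    assert len(summary.oncoprint) == 15
    # conservation: sample-gene mutated pairs in the oncoprint equal the
    # frequency table's per-gene sample counts
    mutation_labels = {"missense", "truncating", "frameshift"}
    pairs = sum(
        1
        for cells in summary.oncoprint.values()
        for label in cells.values()
        if set(label.split(";")) & mutation_labels
    )
    assert pairs == sum(
        row["n_samples_mutated"] for row in summary.gene_variant_freq.values()
    )
    # samples without alterations still appear as empty columns
    assert summary.oncoprint["MBC06"].keys() == {"ARID2"}


def test_duplicate_sample_id_rejected(fixture_profiles, fixture_cohort):
    with pytest.raises(ValueError, match="duplicate"):
        summarize_cohort(fixture_profiles + fixture_profiles[:1], fixture_cohort.metas)


def test_empty_cohort_no_division_by_zero():
    s = summarize_cohort([], [])
    assert s.n_samples == 0
    assert s.percent_actionable is None


def test_report_round_trip(summary, tmp_path):
    write_report(summary, tmp_path)
    assert read_report(tmp_path / "summary.json") == summary
    assert (tmp_path / "oncoprint.tsv").exists()
    assert (tmp_path / "gene_variant_freq.tsv").exists()


@pytest.mark.parametrize(
    "value, expected", [(73.333, 73.3), (86.65, 86.7), (28.571, 28.6), (0.05, 0.1)]
)
def test_display_rounding_half_up(value, expected):
    assert round_half_up(value, 1) == expected


def test_simulated_gene_frequencies_match_implanted(cfg, kb):
    from oncopanel import SimulationConfig, build_sample_profile, simulate_cohort

    sim = simulate_cohort(SimulationConfig(seed=13, n_samples=10))
    metas = {m.sample_id: m for m in sim.metas}
    profiles = [
        build_sample_profile(
            sid, sim.variants[sid], sim.cnv_calls[sid], sim.msi_observations[sid],
            metas[sid], sim.panel, cfg, kb,
        )
        for sid in sim.sample_ids
    ]
    summary = summarize_cohort(profiles, sim.metas)
    implanted: dict[str, set] = {}
    key_to_gene = {}
    for sid in sim.sample_ids:
        for v in sim.variants[sid]:
            key_to_gene[(sid, v.key)] = v.gene
        for k in sim.truth.drivers[sid]:
            implanted.setdefault(key_to_gene[(sid, k)], set()).add(sid)
    assert {
        g: row["n_samples_mutated"] for g, row in summary.gene_variant_freq.items()
    } == {g: len(s) for g, s in implanted.items()}
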