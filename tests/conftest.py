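import pytest
from hypothesis import settings

from oncopanel import (
    AnnotatedVariant,
    ThresholdConfig,
    build_sample_profile,
    default_kb,
    emit_paper_fixture,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def fixture_cohort():
    return emit_paper_fixture()


@pytest.fixture(scope="session")
def kb():
    return default_kb()


@pytest.fixture(scope="session")
def fixture_profiles(fixture_cohort, cfg, kb):
    """All 15 fixture samples pushed through the full pipeline."""
    metas = {m.sample_id: m for m in fixture_cohort.metas}
    return [
        build_sample_profile(
            sid,
            fixture_cohort.variants[sid],
            fixture_cohort.cnv_calls[sid],
            fixture_cohort.msi_observations[sid],
            metas[sid],
            fixture_cohort.panel,
            cfg,
            kb,
        )
        for sid in fixture_cohort.sample_ids
    ]


def make_variant(**overrides):
    """A driver-passing variant unless overridden."""
    base = dict(
        sample_id="s1",
        chrom="chr3",
        pos=178_952_085,
        ref="A",
        alt="G",
        gene="PIK3CA",
        consequence="missense",
        vaf=0.35,
        depth=500,
        popmax_af=0.0,
        cgc_somatic=True,
        cosmic_pathogenic=True,
        filter_status="PASS",
        hgvs_c="c.3140A>G",
        hgvs_p="p.His1047Arg",
    )
    base.update(overrides)
    return AnnotatedVariant(**base)
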