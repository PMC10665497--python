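import pytest

from exotriage import (
    AnnotatedVariant,
    GenePanel,
    Genotype,
    build_replication_cohort,
    generate_replication_fixture,
    run_cohort,
)


def make_variant(**overrides) -> AnnotatedVariant:
    """A valid rare missense variant; override fields per test."""
    base = dict(
        case_id="CASE1",
        chrom="1",
        pos=1000,
        ref="A",
        alt="G",
        gene_symbol="GENE1",
        consequence="missense_variant",
        genotype=Genotype.HETEROZYGOUS,
    )
    base.update(overrides)
    return AnnotatedVariant(**base)


@pytest.fixture
def small_panel() -> GenePanel:
    return GenePanel(
        name="test",
        genes=frozenset({"STAC3", "MTM1", "GENE1", "GENE2"}),
        founder_variant_genes=frozenset({"STAC3"}),
        inheritance_modes={
            "STAC3": "autosomal_recessive",
            "MTM1": "x_linked_recessive",
            "GENE1": "autosomal_dominant",
        },
    )


@pytest.fixture(scope="session")
def replication_cohort():
    """In-memory 32-case replication cohort, built once per session."""
    return build_replication_cohort(seed=11)


@pytest.fixture(scope="session")
def replication_result(replication_cohort):
    manifest, variants_by_case, nicu, ddg2p, config = replication_cohort
    return run_cohort(manifest, variants_by_case, nicu, ddg2p, config), manifest


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """On-disk replication fixture (VCFs + manifest + panels + truth)."""
    out = tmp_path_factory.mktemp("replication")
    paths = generate_replication_fixture(out, seed=11)
    return paths
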