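"""Tier filters, frequency prefilter, prioritization and zygosity rules."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exotriage import (
    ClinvarSignificance,
    ConsistencyVerdict,
    Genotype,
    maf_prefilter,
    prioritize,
    tier1_panel_filter,
    tier2_clinvar_filter,
    tier3_ddg2p_filter,
    zygosity_consistent,
)
from exotriage.errors import ConfigError, DataInconsistencyError
from exotriage.filters import chrom_sort_key, prioritization_key

from conftest import make_variant

# --- hypothesis strategy for small random variant sets ---------------------

_GENES = ["STAC3", "MTM1", "GENE1", "GENE2", "GENE3", "GENE4"]
_CONSEQUENCES = [
    "stop_gained", "frameshift_variant", "missense_variant",
    "synonymous_variant", "intron_variant", "splice_region_variant",
]


@st.composite
def variants(draw):
    gene = draw(st.sampled_from(_GENES))
    chrom = "X" if gene == "MTM1" else draw(st.sampled_from(["1", "2", "7", "22"]))
    genotype = draw(
        st.sampled_from(
            [Genotype.HETEROZYGOUS, Genotype.HOMOZYGOUS_ALT]
            + ([Genotype.HEMIZYGOUS] if chrom == "X" else [])
        )
    )
    maf = draw(st.one_of(st.none(), st.floats(0.0, 0.5, allow_nan=False)))
    return make_variant(
        chrom=chrom,
        pos=draw(st.integers(1, 10_000_000)),
        gene_symbol=gene,
        consequence=draw(st.sampled_from(_CONSEQUENCES)),
        genotype=genotype,
        maf_global=maf,
        clinvar_significance=draw(st.sampled_from(list(ClinvarSignificance))),
        clinvar_stars=None,
        cadd_phred=draw(st.one_of(st.none(), st.floats(0, 40, allow_nan=False))),
        revel=draw(st.one_of(st.none(), st.floats(0, 1, allow_nan=False))),
    )


variant_lists = st.lists(variants(), max_size=12)

# module-level panel for property tests (hypothesis forbids function-scoped
# fixtures inside @given)
from exotriage import GenePanel  # noqa: E402

_PANEL = GenePanel(
    name="prop",
    genes=frozenset({"STAC3", "MTM1", "GENE1", "GENE2"}),
    founder_variant_genes=frozenset({"STAC3"}),
)


class TestTierFilters:
    def test_panel_member_retained(self, small_panel):
        v = make_variant(gene_symbol="STAC3", genotype=Genotype.HOMOZYGOUS_ALT)
        assert tier1_panel_filter([v], small_panel) == [v]

    def test_non_member_removed(self, small_panel):
        v = make_variant(gene_symbol="TRPV4")
        assert tier1_panel_filter([v], small_panel) == []

    def test_hand_counted_fixture(self, small_panel):
        """10 variants across 6 genes; the panel covers 4 of them."""
        genes = ["STAC3", "TRPV4", "GENE1", "GENE1", "SHOC2",
                 "GENE2", "NOPE1", "NOPE2", "NOPE2", "NOPE3"]
        vs = [make_variant(gene_symbol=g, pos=100 + i) for i, g in enumerate(genes)]
        kept = tier1_panel_filter(vs, small_panel)
        assert len(kept) == 4
        assert [v.gene_symbol for v in kept] == ["STAC3", "GENE1", "GENE1", "GENE2"]

    @pytest.mark.parametrize(
        "sig,retained",
        [
            (ClinvarSignificance.PATHOGENIC, True),
            (ClinvarSignificance.LIKELY_PATHOGENIC, True),
            (ClinvarSignificance.UNCERTAIN, True),
            (ClinvarSignificance.CONFLICTING, True),
            (ClinvarSignificance.LIKELY_BENIGN, False),
            (ClinvarSignificance.BENIGN, False),
            (ClinvarSignificance.ABSENT, False),
        ],
    )
    def test_clinvar_filter_categories(self, sig, retained):
        v = make_variant(clinvar_significance=sig)
        assert (tier2_clinvar_filter([v]) == [v]) is retained

    def test_ddg2p_hand_count(self, small_panel):
        genes = ["GENE1", "GENE2", "NOPE", "STAC3", "NOPE", "MTM1", "NOPE", "GENE1"]
        chroms = ["1"] * 5 + ["X"] + ["1", "2"]
        vs = [make_variant(gene_symbol=g, chrom=c, pos=10 + i)
              for i, (g, c) in enumerate(zip(genes, chroms))]
        assert len(tier3_ddg2p_filter(vs, small_panel)) == 5

    @settings(max_examples=100, derandomize=True)
    @given(vs=variant_lists)
    def test_filters_are_subset_operations(self, vs):
        """Every filter returns a subsequence of its input, unmutated."""
        for out in (
            tier1_panel_filter(vs, _PANEL),
            tier2_clinvar_filter(vs),
            tier3_ddg2p_filter(vs, _PANEL),
            maf_prefilter(vs),
        ):
            it = iter(vs)
            assert all(any(o is x for x in it) for o in out)  # ordered subsequence

    @settings(max_examples=100, derandomize=True)
    @given(vs=variant_lists)
    def test_panel_outputs_contain_only_panel_genes(self, vs):
        for v in tier1_panel_filter(vs, _PANEL):
            assert v.gene_symbol.upper() in _PANEL.genes


class TestMafPrefilter:
    def test_founder_gene_exempt(self):
        v = make_variant(gene_symbol="STAC3", maf_african=0.04,
                         genotype=Genotype.HOMOZYGOUS_ALT)
        assert maf_prefilter([v], founder_genes={"STAC3"}) == [v]
        assert maf_prefilter([v]) == []

    def test_common_variant_removed(self):
        v = make_variant(maf_global=0.20)
        assert maf_prefilter([v]) == []

    def test_hand_applied_retention_pattern(self):
        """MAFs {absent, 1e-5, 5e-4, 0.02, 0.08, 0.3} at cutoffs 0.01/0.03.

        Heterozygous calls screen at 0.01, homozygous at 0.03; absent MAF is
        always retained.
        """
        mafs = [None, 1e-5, 5e-4, 0.02, 0.08, 0.3]
        gts = [Genotype.HETEROZYGOUS, Genotype.HETEROZYGOUS, Genotype.HOMOZYGOUS_ALT,
               Genotype.HOMOZYGOUS_ALT, Genotype.HETEROZYGOUS, Genotype.HOMOZYGOUS_ALT]
        vs = [make_variant(pos=1 + i, maf_global=m, genotype=g)
              for i, (m, g) in enumerate(zip(mafs, gts))]
        kept = maf_prefilter(vs, dominant_cutoff=0.01, recessive_cutoff=0.03)
        assert [v.pos for v in kept] == [1, 2, 3, 4]  # 0.08 het and 0.3 hom fail

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ConfigError):
            maf_prefilter([], dominant_cutoff=1.5)


class TestPrioritize:
    def test_singleton(self):
        v = make_variant()
        assert prioritize([v]) == [v]

    def test_matches_oracle_comparator_sort(self):
        """Hand-built fixture with distinct keys must equal a brute-force
        sort on the documented comparator."""
        vs = [
            make_variant(pos=10, clinvar_significance=ClinvarSignificance.ABSENT,
                         consequence="missense_variant", maf_global=1e-3),
            make_variant(pos=20, clinvar_significance=ClinvarSignificance.PATHOGENIC,
                         clinvar_stars=2, consequence="synonymous_variant"),
            make_variant(pos=30, consequence="stop_gained", maf_global=None),
            make_variant(pos=40, consequence="missense_variant", maf_global=1e-6,
                         cadd_phred=30.0, revel=0.9),
        ]

        def oracle(v):
            k = prioritization_key(v)
            return (not k.clinvar_plp_flag, k.severity_rank, k.maf_for_ranking,
                    -k.deleterious_tool_count, k.position_key)

        assert prioritize(vs) == sorted(vs, key=oracle)
        # ClinVar-flagged variant leads despite mild consequence
        assert prioritize(vs)[0].pos == 20

    @settings(max_examples=100, derandomize=True)
    @given(vs=variant_lists)
    def test_permutation_and_idempotence(self, vs):
        once = prioritize(vs)
        assert sorted(map(id, once)) == sorted(map(id, vs))
        assert prioritize(once) == once

    def test_stability_on_identical_keys(self):
        a = make_variant(pos=100)
        b = make_variant(pos=100)  # identical key fields
        result = prioritize([a, b])
        assert result[0] is a and result[1] is b

    def test_chromosome_ordering(self):
        assert chrom_sort_key("chr2") < chrom_sort_key("10")
        assert chrom_sort_key("22") < chrom_sort_key("X") < chrom_sort_key("MT")


class TestZygosityConsistency:
    def test_xlr_hemizygous_male(self):
        v = make_variant(chrom="X", gene_symbol="MTM1", consequence="stop_gained",
                         genotype=Genotype.HEMIZYGOUS)
        assert zygosity_consistent(v, "male", "x_linked_recessive") is (
            ConsistencyVerdict.CONSISTENT
        )

    def test_ad_heterozygous(self):
        v = make_variant(gene_symbol="COL2A1")
        assert zygosity_consistent(v, "female", "autosomal_dominant") is (
            ConsistencyVerdict.CONSISTENT
        )

    def test_ar_single_het_is_carrier(self):
        v = make_variant()
        assert zygosity_consistent(v, "male", "autosomal_recessive", [v]) is (
            ConsistencyVerdict.CARRIER_ONLY
        )

    def test_ar_two_hets_provisional_compound(self):
        a = make_variant(pos=100)
        b = make_variant(pos=200)
        verdict = zygosity_consistent(a, "female", "autosomal_recessive", [a, b])
        assert verdict is ConsistencyVerdict.PROVISIONAL_COMPOUND_HET

    def test_ar_homozygous_consistent(self):
        v = make_variant(genotype=Genotype.HOMOZYGOUS_ALT)
        assert zygosity_consistent(v, "female", "autosomal_recessive") is (
            ConsistencyVerdict.CONSISTENT
        )

    def test_xlr_heterozygous_female_is_carrier(self):
        v = make_variant(chrom="X", genotype=Genotype.HETEROZYGOUS)
        assert zygosity_consistent(v, "female", "x_linked_recessive") is (
            ConsistencyVerdict.CARRIER_ONLY
        )

    def test_hemizygous_female_is_data_error(self):
        v = make_variant(chrom="X", genotype=Genotype.HEMIZYGOUS)
        with pytest.raises(DataInconsistencyError):
            zygosity_consistent(v, "female", "x_linked_recessive")

    @settings(max_examples=100, derandomize=True)
    @given(vs=variant_lists)
    def test_single_het_never_consistent_under_ar(self, vs):
        for v in vs:
            if v.genotype is not Genotype.HETEROZYGOUS:
                continue
            verdict = zygosity_consistent(v, "male", "autosomal_recessive", [v])
            assert verdict is not ConsistencyVerdict.CONSISTENT
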