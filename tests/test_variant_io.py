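"""VCF ingestion, consequence selection and variant-table round-trips."""

import pytest

from exotriage import (
    AnnotatedVariant,
    ClinvarSignificance,
    CsqFieldMap,
    Genotype,
    read_annotated_vcf,
    read_variant_table,
    select_primary_consequence,
    write_variant_table,
)
from exotriage.errors import InputError, UnsupportedInputError
from exotriage.variant_io import (
    _minimal_representation,
    normalize_clinvar_significance,
    severity_rank,
)

from conftest import make_variant

CSQ_FMT = (
    "SYMBOL|Consequence|HGVSc|HGVSp|gnomAD_AF|gnomAD_AFR_AF|CLIN_SIG|"
    "ClinVar_STARS|CADD_PHRED|REVEL|BayesDel|MetaRNN"
)

HEADER = "\n".join(
    [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        "##contig=<ID=19>",
        "##contig=<ID=X>",
        f'##INFO=<ID=CSQ,Number=.,Type=String,Description="Format: {CSQ_FMT}">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
    ]
)


def write_vcf(path, sample_records, sample="S1"):
    body = "\n".join(sample_records)
    text = HEADER + f"\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n"
    if body:
        text += body + "\n"
    path.write_text(text)
    return path


def csq(symbol="GENE1", consequence="missense_variant", **kw):
    fields = {
        "HGVSc": "", "HGVSp": "", "gnomAD_AF": "", "gnomAD_AFR_AF": "",
        "CLIN_SIG": "", "ClinVar_STARS": "", "CADD_PHRED": "", "REVEL": "",
        "BayesDel": "", "MetaRNN": "",
    }
    fields.update(kw)
    return "|".join([symbol, consequence] + [fields[k] for k in list(fields)])


class TestReadAnnotatedVcf:
    def test_header_only_yields_empty_list(self, tmp_path):
        path = write_vcf(tmp_path / "empty.vcf", [])
        assert read_annotated_vcf(path, case_id="C") == []

    def test_record_and_alt_enumeration(self, tmp_path):
        """3 records, one biallelic with both alts carried -> 4 variants."""
        recs = [
            f"1\t100\t.\tA\tG\t.\tPASS\tCSQ={csq()}\tGT:DP\t0/1:50",
            f"1\t200\t.\tC\tT,G\t.\tPASS\tCSQ={csq()}\tGT:DP\t1/2:60",
            f"1\t300\t.\tG\tA\t.\tPASS\tCSQ={csq()}\tGT:DP\t1/1:70",
        ]
        variants = read_annotated_vcf(write_vcf(tmp_path / "m.vcf", recs), case_id="C")
        assert len(variants) == 4
        # the 1/2 record splits into two heterozygous-against-alt calls
        split = [v for v in variants if v.pos == 200]
        assert {v.alt for v in split} == {"T", "G"}
        assert all(v.genotype is Genotype.HETEROZYGOUS for v in split)

    def test_homozygous_genotype_mapping(self, tmp_path):
        """A 1/1 NPHS1 call maps to homozygous_alt, as in the recessive
        congenital-nephrotic-syndrome diagnosis."""
        recs = [
            "19\t36318879\t.\tG\tA\t.\tPASS\t"
            f"CSQ={csq('NPHS1', 'missense_variant', CLIN_SIG='pathogenic', ClinVar_STARS='2')}"
            "\tGT:DP\t1/1:89",
        ]
        (v,) = read_annotated_vcf(write_vcf(tmp_path / "h.vcf", recs), case_id="NE033")
        assert v.gene_symbol == "NPHS1"
        assert v.genotype is Genotype.HOMOZYGOUS_ALT
        assert v.clinvar_significance is ClinvarSignificance.PATHOGENIC
        assert v.clinvar_stars == 2
        assert v.read_depth == 89

    def test_haploid_call_on_x_is_hemizygous(self, tmp_path):
        recs = [f"X\t500\t.\tC\tT\t.\tPASS\tCSQ={csq('MTM1','stop_gained')}\tGT:DP\t1:47"]
        (v,) = read_annotated_vcf(write_vcf(tmp_path / "x.vcf", recs), case_id="C")
        assert v.genotype is Genotype.HEMIZYGOUS

    def test_record_without_annotation_is_skipped(self, tmp_path):
        recs = [
            "1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP\t0/1:50",
            f"1\t200\t.\tC\tT\t.\tPASS\tCSQ={csq()}\tGT:DP\t0/1:50",
        ]
        variants = read_annotated_vcf(write_vcf(tmp_path / "s.vcf", recs), case_id="C")
        assert [v.pos for v in variants] == [200]

    def test_reference_genotype_not_emitted(self, tmp_path):
        recs = [f"1\t100\t.\tA\tG\t.\tPASS\tCSQ={csq()}\tGT:DP\t0/0:50"]
        assert read_annotated_vcf(write_vcf(tmp_path / "r.vcf", recs), case_id="C") == []

    def test_missing_numeric_fields_stay_absent(self, tmp_path):
        recs = [f"1\t100\t.\tA\tG\t.\tPASS\tCSQ={csq(REVEL='', CADD_PHRED='12.5')}\tGT:DP\t0/1:50"]
        (v,) = read_annotated_vcf(write_vcf(tmp_path / "a.vcf", recs), case_id="C")
        assert v.revel is None
        assert v.cadd_phred == 12.5
        assert v.maf_global is None

    def test_multi_sample_rejected(self, tmp_path):
        path = tmp_path / "two.vcf"
        path.write_text(
            HEADER
            + "\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            + f"1\t100\t.\tA\tG\t.\tPASS\tCSQ={csq()}\tGT\t0/1\t0/1\n"
        )
        with pytest.raises(UnsupportedInputError):
            read_annotated_vcf(path, case_id="C")

    def test_unreadable_file_is_input_error(self, tmp_path):
        with pytest.raises(InputError):
            read_annotated_vcf(tmp_path / "missing.vcf", case_id="C")


class TestMinimalRepresentation:
    @pytest.mark.parametrize(
        "pos,ref,alt,expected",
        [
            (100, "A", "G", (100, "A", "G")),
            (100, "CAG", "CG", (100, "CA", "C")),     # shared suffix trimmed
            (100, "ATT", "ATTT", (100, "A", "AT")),   # insertion left-aligned
            (100, "ACGT", "AGGT", (101, "C", "G")),   # prefix trimmed, pos shifts
        ],
    )
    def test_trimming(self, pos, ref, alt, expected):
        assert _minimal_representation(pos, ref, alt) == expected


class TestSelectPrimaryConsequence:
    def test_single_block_is_identity(self):
        block = {"symbol": "G", "consequence": "missense_variant"}
        assert select_primary_consequence([block]) is block

    @pytest.mark.parametrize(
        "terms,winner",
        [
            (["synonymous_variant", "missense_variant"], "missense_variant"),
            (["missense_variant", "stop_gained"], "stop_gained"),
            (["intron_variant", "splice_region_variant"], "splice_region_variant"),
        ],
    )
    def test_most_severe_block_wins(self, terms, winner):
        blocks = [{"consequence": t} for t in terms]
        assert select_primary_consequence(blocks)["consequence"] == winner

    def test_canonical_breaks_severity_ties(self):
        blocks = [
            {"consequence": "missense_variant", "canonical": ""},
            {"consequence": "missense_variant", "canonical": "YES"},
        ]
        assert select_primary_consequence(blocks) is blocks[1]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_primary_consequence([])

    def test_compound_terms_rank_by_most_severe_component(self):
        assert severity_rank("missense_variant&splice_region_variant") == severity_rank(
            "missense_variant"
        )


class TestVariantTable:
    def test_empty_list_writes_header_only(self, tmp_path):
        path = tmp_path / "t.tsv"
        assert write_variant_table([], path) == 0
        assert len(path.read_text().splitlines()) == 1

    def test_round_trip_is_exact(self, tmp_path):
        variants = [
            make_variant(),
            make_variant(pos=2000, genotype=Genotype.HOMOZYGOUS_ALT,
                         maf_global=0.004, cadd_phred=25.9, hgvs_c="c.851G>C",
                         clinvar_significance=ClinvarSignificance.PATHOGENIC,
                         clinvar_stars=2, read_depth=124),
            make_variant(chrom="X", pos=47, genotype=Genotype.HEMIZYGOUS),
            make_variant(pos=3000, revel=None, bayesdel=-0.31),
        ]
        path = tmp_path / "t.tsv"
        assert write_variant_table(variants, path) == 4
        assert read_variant_table(path) == variants

    def test_absent_score_serializes_as_missing_token_not_zero(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_variant_table([make_variant(revel=None)], path)
        row = path.read_text().splitlines()[1].split("\t")
        header = path.read_text().splitlines()[0].split("\t")
        assert row[header.index("revel")] == "."


class TestClinvarNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Pathogenic", ClinvarSignificance.PATHOGENIC),
            ("likely pathogenic", ClinvarSignificance.LIKELY_PATHOGENIC),
            ("Pathogenic/Likely_pathogenic", ClinvarSignificance.LIKELY_PATHOGENIC),
            ("Conflicting_interpretations_of_pathogenicity", ClinvarSignificance.CONFLICTING),
            ("Uncertain_significance", ClinvarSignificance.UNCERTAIN),
            ("benign", ClinvarSignificance.BENIGN),
            (None, ClinvarSignificance.ABSENT),
            (".", ClinvarSignificance.ABSENT),
        ],
    )
    def test_normalization(self, raw, expected):
        assert normalize_clinvar_significance(raw) is expected


class TestInvariants:
    def test_stars_require_assertion(self):
        with pytest.raises(ValueError):
            make_variant(clinvar_stars=2)  # no significance set

    def test_hemizygous_requires_sex_chromosome(self):
        with pytest.raises(ValueError):
            make_variant(chrom="7", genotype=Genotype.HEMIZYGOUS)

    def test_ref_must_differ_from_alt(self):
        with pytest.raises(ValueError):
            make_variant(ref="A", alt="A")

    def test_maf_bounds(self):
        with pytest.raises(ValueError):
            make_variant(maf_global=1.2)

    def test_csq_map_requires_symbol_and_consequence(self):
        with pytest.raises(ValueError):
            CsqFieldMap(field_names=("A", "B"), roles={"symbol": "A"})
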