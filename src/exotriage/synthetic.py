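"""Seeded synthetic cohorts for exercising the triage cascade end to end.

The study whose workflow this package implements deposited only its
interpreted variants, not raw exomes, so testing the pipeline requires a
generator that emulates its inputs: per-case annotated single-sample VCFs
with realistic frequency/consequence/score structure, plus a canonical
*replication fixture* — a 32-infant cohort whose site/sex/referrer/ancestry/
indication margins match the published cohort table and into which the seven
published diagnoses (STAC3, MTM1, COL2A1, SHOC2, OCRL, NPHS1, TRPV4) are
planted with their reported zygosity, ClinVar status, curated evidence codes
and discovery tier.

Background variants are *benign-consistent by construction*: each one is
either common (so the frequency prefilter or BA1 removes it from contention)
or rare with a benign/absent ClinVar record and sub-threshold in-silico
scores, so annotation-derived evidence can never exceed one supporting point
(PM2) — far below the likely-pathogenic threshold. Planted causatives are
therefore the only variants the cascade can call, and the truth manifest is
an exact oracle.

All randomness flows from a single integer seed; per-case streams are derived
deterministically, so regeneration with the same seed is file-for-file
identical. Genomic coordinates are synthetic (plausible GRCh37-like offsets);
coordinate realism is a non-goal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .acmg import parse_evidence_string
from .cascade import Tier, TriageConfig
from .errors import ConfigError
from .filters import TIER2_RETAINED
from .gene_panels import GenePanel
from .variant_io import AnnotatedVariant, ClinvarSignificance, Genotype

# ---------------------------------------------------------------------------
# Synthetic gene map (GRCh37-like coordinates)
# ---------------------------------------------------------------------------

#: symbol -> (contig, transcription-start-like anchor). Positions are
#: plausible but synthetic; only contig identity (autosome vs X) matters.
GENE_COORDS: dict[str, tuple[str, int]] = {
    # genes of the seven published diagnoses
    "STAC3": ("12", 57243000),
    "MTM1": ("X", 149737047),
    "COL2A1": ("12", 48366748),
    "SHOC2": ("10", 112723000),
    "OCRL": ("X", 128674000),
    "NPHS1": ("19", 36317500),
    "TRPV4": ("12", 110221000),
    # autosomal background genes
    "CFTR": ("7", 117120016),
    "ABCA4": ("1", 94458393),
    "TTN": ("2", 179390716),
    "BRCA2": ("13", 32889616),
    "FBN1": ("15", 48700502),
    "MYH7": ("14", 23881946),
    "SCN1A": ("2", 166845670),
    "PAH": ("12", 103232103),
    "GJB2": ("13", 20761608),
    "HBB": ("11", 5246695),
    "LDLR": ("19", 11200037),
    "MYBPC3": ("11", 47352956),
    "PKD1": ("16", 2138710),
    "COL1A1": ("17", 48260649),
    "RYR1": ("19", 38924339),
    "PTPN11": ("12", 112856154),
    "NF1": ("17", 29421944),
    "TSC2": ("16", 2097989),
    "KCNQ1": ("11", 2466220),
    "LAMA2": ("6", 129204285),
    "POMT1": ("9", 134378289),
    "GAA": ("17", 78075354),
    "SMPD1": ("11", 6411643),
    "ASPA": ("17", 3379616),
    "ACADVL": ("17", 7120443),
    "ETFA": ("15", 76508871),
    "GBE1": ("3", 81538849),
    "SLC26A4": ("7", 107301080),
    "USH2A": ("1", 215796235),
    "MYO7A": ("11", 76839310),
    "ARID1B": ("6", 157099063),
    "ANKRD11": ("16", 89334037),
    "KMT2A": ("11", 118307205),
    "CHD7": ("8", 61591323),
    "CREBBP": ("16", 3775055),
    "EP300": ("22", 41488614),
    "DYRK1A": ("21", 38739859),
    "SATB2": ("2", 200134223),
}

PLANTED_GENES = ("STAC3", "MTM1", "COL2A1", "SHOC2", "OCRL", "NPHS1", "TRPV4")
#: Background variants never land in the diagnosis genes.
BACKGROUND_GENE_POOL = tuple(
    g for g in GENE_COORDS if g not in PLANTED_GENES
)

#: Genes whose disease mechanism is loss of function (PVS1-eligible).
LOF_MECHANISM_GENES = frozenset({"MTM1", "OCRL"})

_NICU_PANEL_MODES = {
    "STAC3": "autosomal_recessive",
    "MTM1": "x_linked_recessive",
    "COL2A1": "autosomal_dominant",
    "OCRL": "x_linked_recessive",
    "NPHS1": "autosomal_recessive",
    "RYR1": "autosomal_recessive",
    "PTPN11": "autosomal_dominant",
    "NF1": "autosomal_dominant",
    "LAMA2": "autosomal_recessive",
    "POMT1": "autosomal_recessive",
    "GAA": "autosomal_recessive",
    "ACADVL": "autosomal_recessive",
    "ETFA": "autosomal_recessive",
    "KCNQ1": "autosomal_dominant",
    "SCN1A": "autosomal_dominant",
    "PAH": "autosomal_recessive",
    "GJB2": "autosomal_recessive",
    "MYH7": "autosomal_dominant",
    "MYBPC3": "autosomal_dominant",
    "TSC2": "autosomal_dominant",
}

_DDG2P_PANEL_MODES = {
    "SHOC2": "autosomal_dominant",
    "TRPV4": "autosomal_dominant",
    "COL2A1": "autosomal_dominant",
    "PTPN11": "autosomal_dominant",
    "NF1": "autosomal_dominant",
    "TSC2": "autosomal_dominant",
    "SCN1A": "autosomal_dominant",
    "ARID1B": "autosomal_dominant",
    "ANKRD11": "autosomal_dominant",
    "KMT2A": "autosomal_dominant",
    "CHD7": "autosomal_dominant",
    "CREBBP": "autosomal_dominant",
    "EP300": "autosomal_dominant",
    "DYRK1A": "autosomal_dominant",
    "SATB2": "autosomal_dominant",
}


def fixture_nicu_panel() -> GenePanel:
    """Small stand-in for the study's 1,127-gene NICU/African virtual panel.

    Synthetic: contains the five diagnosis genes discovered at tier 1 (and
    deliberately excludes SHOC2 and TRPV4, which the study found at tier 2)
    plus a spread of neonatal-disease background genes. STAC3, GJB2 and PAH
    carry the founder-variant flag.
    """
    return GenePanel(
        name="NICU_African_fixture",
        genes=frozenset(_NICU_PANEL_MODES),
        founder_variant_genes=frozenset({"STAC3", "GJB2", "PAH"}),
        inheritance_modes=dict(_NICU_PANEL_MODES),
        version="fixture-1",
    )


def fixture_ddg2p_panel() -> GenePanel:
    """Small stand-in for the 2,313-gene DDG2P panel (synthetic subset)."""
    return GenePanel(
        name="DDG2P_fixture",
        genes=frozenset(_DDG2P_PANEL_MODES),
        inheritance_modes=dict(_DDG2P_PANEL_MODES),
        version="fixture-1",
    )


# ---------------------------------------------------------------------------
# Planted causative variants (the seven published diagnoses)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedVariantSpec:
    """Full profile of one causative variant to plant into a case."""

    case_id: str
    gene_symbol: str
    consequence: str
    genotype: Genotype
    inheritance_mode: str
    clinvar_significance: ClinvarSignificance
    clinvar_stars: int
    evidence_code_tokens: str
    curated_label: str
    expected_tier: Tier
    hgvs_c: str
    hgvs_p: str
    ref: str
    alt: str
    cdna_offset: int  # synthetic: variant sits at gene anchor + offset
    read_depth: int
    site: str
    sex: str
    referrer: str
    ancestry: str
    indication: str
    maf_global: float | None = None
    maf_african: float | None = None
    cadd_phred: float | None = None
    revel: float | None = None
    bayesdel: float | None = None
    metarnn: float | None = None

    def __post_init__(self) -> None:
        for token in self.evidence_code_tokens.split(","):
            parse_evidence_string(token)  # raises EvidenceParseError if bad


#: The seven diagnosed participants: gene, zygosity, ClinVar status, curated
#: evidence codes, discovery tier and demographic labels as published.
REPLICATION_PLANTED_SPECS: tuple[PlantedVariantSpec, ...] = (
    PlantedVariantSpec(
        case_id="NE001", gene_symbol="STAC3", consequence="missense_variant",
        genotype=Genotype.HOMOZYGOUS_ALT, inheritance_mode="autosomal_recessive",
        clinvar_significance=ClinvarSignificance.PATHOGENIC, clinvar_stars=2,
        evidence_code_tokens="PM3_strong, PS3, PP3, PP5_supporting",
        curated_label="pathogenic", expected_tier=Tier.PANEL,
        hgvs_c="c.851G>C", hgvs_p="p.Trp284Ser", ref="G", alt="C",
        cdna_offset=851, read_depth=124,
        site="RMMCH", sex="male", referrer="Neonatologist/Paediatrician",
        ancestry="African", indication="Neuromuscular",
        maf_global=0.0006, maf_african=0.004,  # African founder allele
        cadd_phred=25.9, revel=0.77, bayesdel=0.27, metarnn=0.86,
    ),
    PlantedVariantSpec(
        case_id="NE021", gene_symbol="MTM1", consequence="stop_gained",
        genotype=Genotype.HEMIZYGOUS, inheritance_mode="x_linked_recessive",
        clinvar_significance=ClinvarSignificance.PATHOGENIC, clinvar_stars=2,
        evidence_code_tokens="PVS1, PM2_supporting, PP5_supporting",
        curated_label="pathogenic", expected_tier=Tier.PANEL,
        hgvs_c="c.664C>T", hgvs_p="p.Arg222Ter", ref="C", alt="T",
        cdna_offset=664, read_depth=47,
        site="RMMCH", sex="male", referrer="Neonatologist/Paediatrician",
        ancestry="Other", indication="Neuromuscular",
        cadd_phred=36.0,
    ),
    PlantedVariantSpec(
        case_id="NE022", gene_symbol="COL2A1", consequence="missense_variant",
        genotype=Genotype.HETEROZYGOUS, inheritance_mode="autosomal_dominant",
        # joint P/LP assertion, normalized to the weaker member
        clinvar_significance=ClinvarSignificance.LIKELY_PATHOGENIC, clinvar_stars=2,
        evidence_code_tokens="PM5, PM1, PM2_supporting, PP3, PP2, PP5_supporting",
        curated_label="likely_pathogenic", expected_tier=Tier.PANEL,
        hgvs_c="c.3589G>A", hgvs_p="p.Gly1197Ser", ref="G", alt="A",
        cdna_offset=3589, read_depth=85,
        site="NMCH", sex="female", referrer="Geneticist",
        ancestry="African", indication="Skeletal",
        cadd_phred=29.8, revel=0.92, bayesdel=0.41, metarnn=0.93,
    ),
    PlantedVariantSpec(
        case_id="NE026", gene_symbol="SHOC2", consequence="missense_variant",
        genotype=Genotype.HETEROZYGOUS, inheritance_mode="autosomal_dominant",
        clinvar_significance=ClinvarSignificance.PATHOGENIC, clinvar_stars=3,
        evidence_code_tokens=(
            "PS2_very strong, PS4, PS3_moderate, PM2_supporting, PP2, PP5_supporting"
        ),
        curated_label="pathogenic", expected_tier=Tier.CLINVAR,
        hgvs_c="c.4A>G", hgvs_p="p.Ser2Gly", ref="A", alt="G",
        cdna_offset=4, read_depth=34,
        site="RMMCH", sex="male", referrer="Neonatologist/Paediatrician",
        ancestry="African", indication="Developmental",
        cadd_phred=24.3, revel=0.88, bayesdel=0.35, metarnn=0.90,
    ),
    PlantedVariantSpec(
        case_id="NE029", gene_symbol="OCRL", consequence="stop_gained",
        genotype=Genotype.HEMIZYGOUS, inheritance_mode="x_linked_recessive",
        clinvar_significance=ClinvarSignificance.PATHOGENIC, clinvar_stars=2,
        evidence_code_tokens="PVS1_strong, PM2_supporting, PP5_supporting",
        # curator printed "pathogenic"; the points scale computes
        # likely_pathogenic and the cascade flags the discrepancy
        curated_label="pathogenic", expected_tier=Tier.PANEL,
        hgvs_c="c.1621C>T", hgvs_p="p.Arg541Ter", ref="C", alt="T",
        cdna_offset=1621, read_depth=16,
        site="RMMCH", sex="male", referrer="Geneticist",
        ancestry="Mixed", indication="Multiple congenital anomalies",
        cadd_phred=38.0,
    ),
    PlantedVariantSpec(
        case_id="NE033", gene_symbol="NPHS1", consequence="missense_variant",
        genotype=Genotype.HOMOZYGOUS_ALT, inheritance_mode="autosomal_recessive",
        clinvar_significance=ClinvarSignificance.PATHOGENIC, clinvar_stars=2,
        evidence_code_tokens="PM3_strong, PM1, PP5_supporting",
        curated_label="likely_pathogenic", expected_tier=Tier.PANEL,
        hgvs_c="c.1379G>A", hgvs_p="p.Arg460Gln", ref="G", alt="A",
        cdna_offset=1379, read_depth=89,
        site="RMMCH", sex="female", referrer="Geneticist",
        ancestry="African", indication="Renal",
        maf_global=8e-6,
        cadd_phred=29.6, revel=0.83, bayesdel=0.30, metarnn=0.88,
    ),
    PlantedVariantSpec(
        case_id="NE034", gene_symbol="TRPV4", consequence="missense_variant",
        genotype=Genotype.HETEROZYGOUS, inheritance_mode="autosomal_dominant",
        clinvar_significance=ClinvarSignificance.PATHOGENIC, clinvar_stars=2,
        evidence_code_tokens="PS4, PS3, PM5, PM1, PP5_supporting",
        curated_label="pathogenic", expected_tier=Tier.CLINVAR,
        hgvs_c="c.806G>A", hgvs_p="p.Arg269His", ref="G", alt="A",
        cdna_offset=806, read_depth=73,
        site="RMMCH", sex="female", referrer="Neonatologist/Paediatrician",
        ancestry="African", indication="Skeletal",
        maf_global=4e-6,
        cadd_phred=27.1, revel=0.85, bayesdel=0.33, metarnn=0.91,
    ),
)


def spec_to_variant(spec: PlantedVariantSpec) -> AnnotatedVariant:
    chrom, anchor = GENE_COORDS[spec.gene_symbol]
    return AnnotatedVariant(
        case_id=spec.case_id,
        chrom=chrom,
        pos=anchor + spec.cdna_offset,
        ref=spec.ref,
        alt=spec.alt,
        gene_symbol=spec.gene_symbol,
        consequence=spec.consequence,
        genotype=spec.genotype,
        hgvs_c=spec.hgvs_c,
        hgvs_p=spec.hgvs_p,
        maf_global=spec.maf_global,
        maf_african=spec.maf_african,
        clinvar_significance=spec.clinvar_significance,
        clinvar_stars=spec.clinvar_stars,
        cadd_phred=spec.cadd_phred,
        revel=spec.revel,
        bayesdel=spec.bayesdel,
        metarnn=spec.metarnn,
        read_depth=spec.read_depth,
    )


def plant_causative(
    case_variants: Sequence[AnnotatedVariant],
    spec: PlantedVariantSpec,
    nicu_panel: GenePanel,
    ddg2p_panel: GenePanel,
) -> list[AnnotatedVariant]:
    """Insert one causative variant into a case's variant set.

    Validates that the spec is compatible with its expected discovery tier:
    a tier-1 expectation requires panel membership; a tier-2 expectation
    requires a retained ClinVar category *and* absence from the tier-1 panel
    (otherwise tier 1 would claim it first); tier 3 likewise requires DDG2P
    membership and invisibility to tiers 1 and 2.
    """
    gene = spec.gene_symbol
    if spec.expected_tier is Tier.PANEL and not nicu_panel.contains(gene):
        raise ConfigError(f"{spec.case_id}: {gene} expected at tier 1 but not on panel")
    if spec.expected_tier is Tier.CLINVAR:
        if nicu_panel.contains(gene):
            raise ConfigError(
                f"{spec.case_id}: {gene} expected at tier 2 but tier-1 panel contains it"
            )
        if spec.clinvar_significance not in TIER2_RETAINED:
            raise ConfigError(
                f"{spec.case_id}: tier-2 expectation incompatible with ClinVar "
                f"{spec.clinvar_significance.value}"
            )
    if spec.expected_tier is Tier.DDG2P:
        if nicu_panel.contains(gene) or spec.clinvar_significance in TIER2_RETAINED:
            raise ConfigError(
                f"{spec.case_id}: {gene} would be claimed before tier 3"
            )
        if not ddg2p_panel.contains(gene):
            raise ConfigError(f"{spec.case_id}: {gene} not on the DDG2P panel")
    return list(case_variants) + [spec_to_variant(spec)]


# ---------------------------------------------------------------------------
# Background generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world of the background generator.

    Defaults: 32 cases (the published cohort size) at 500 benign-consistent
    background variants per case — enough to exercise every filter while
    keeping a full cohort run in seconds. Consequence fractions and the
    rare/common frequency mixture are chosen to resemble a post-QC annotated
    exome at the scale the cascade inspects; they are documented realism, not
    fitted quantities.
    """

    n_cases: int = 32
    background_variants_per_case: int = 500
    seed: int = 2021
    fraction_common: float = 0.30  # common component of the MAF mixture
    fraction_missense: float = 0.45
    fraction_synonymous: float = 0.30
    fraction_null: float = 0.05
    rare_maf_absent_prob: float = 0.40
    clinvar_rare_priors: tuple[tuple[str, float], ...] = (
        ("absent", 0.90), ("benign", 0.03), ("likely_benign", 0.03),
        ("uncertain", 0.03), ("conflicting", 0.01),
    )
    clinvar_common_priors: tuple[tuple[str, float], ...] = (
        ("absent", 0.70), ("benign", 0.20), ("likely_benign", 0.10),
    )

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_common, self.fraction_missense,
            self.fraction_synonymous, self.fraction_null,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ConfigError("all fractions must lie in [0, 1]")
        if self.fraction_missense + self.fraction_synonymous + self.fraction_null > 1.0:
            raise ConfigError("consequence fractions sum to more than 1")
        if self.n_cases < 0 or self.background_variants_per_case < 0:
            raise ConfigError("counts must be non-negative")


_BASES = ("A", "C", "G", "T")
_OTHER_CONSEQUENCES = (
    "intron_variant", "splice_region_variant",
    "3_prime_UTR_variant", "5_prime_UTR_variant",
)
_NULL_BACKGROUND = ("stop_gained", "frameshift_variant")

_SIG_FROM_NAME = {
    "absent": ClinvarSignificance.ABSENT,
    "benign": ClinvarSignificance.BENIGN,
    "likely_benign": ClinvarSignificance.LIKELY_BENIGN,
    "uncertain": ClinvarSignificance.UNCERTAIN,
    "conflicting": ClinvarSignificance.CONFLICTING,
}


def _choice(rng: np.random.Generator, priors: tuple[tuple[str, float], ...]) -> str:
    names = [n for n, _ in priors]
    probs = np.array([p for _, p in priors], dtype=float)
    return names[rng.choice(len(names), p=probs / probs.sum())]


def generate_background(
    case_id: str,
    config: SyntheticConfig | None = None,
    seed: int | None = None,
    case_index: int = 0,
) -> list[AnnotatedVariant]:
    """Generate one case's benign-consistent background variant set.

    Deterministic given (seed, case_index). Every emitted variant is either
    common (MAF drawn from a scaled-Beta component on [0.02, 0.45]) or rare
    (MAF absent or below 1e-4) with benign/absent/uncertain ClinVar status
    and in-silico scores below every deleteriousness cut-off, so that
    annotation-derived evidence never exceeds one supporting point.
    """
    config = config or SyntheticConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, case_index])

    variants: list[AnnotatedVariant] = []
    used_positions: set[tuple[str, int]] = set()
    for _ in range(config.background_variants_per_case):
        gene = BACKGROUND_GENE_POOL[rng.integers(len(BACKGROUND_GENE_POOL))]
        chrom, anchor = GENE_COORDS[gene]
        pos = int(anchor + rng.integers(1, 60000))
        while (chrom, pos) in used_positions:
            pos = int(anchor + rng.integers(1, 60000))
        used_positions.add((chrom, pos))

        u = rng.random()
        if u < config.fraction_missense:
            consequence = "missense_variant"
        elif u < config.fraction_missense + config.fraction_synonymous:
            consequence = "synonymous_variant"
        elif u < config.fraction_missense + config.fraction_synonymous + config.fraction_null:
            consequence = _NULL_BACKGROUND[rng.integers(2)]
        else:
            consequence = _OTHER_CONSEQUENCES[rng.integers(len(_OTHER_CONSEQUENCES))]

        ref = _BASES[rng.integers(4)]
        if consequence == "frameshift_variant":
            alt = ref + _BASES[rng.integers(4)]
        else:
            alt = _BASES[rng.integers(4)]
            while alt == ref:
                alt = _BASES[rng.integers(4)]

        is_common = rng.random() < config.fraction_common
        if is_common:
            maf_global = float(0.02 + 0.43 * rng.beta(2.0, 5.0))
            maf_african = float(min(1.0, maf_global * rng.uniform(0.5, 1.5)))
            sig_name = _choice(rng, config.clinvar_common_priors)
            genotype = (
                Genotype.HOMOZYGOUS_ALT if rng.random() < 0.25 else Genotype.HETEROZYGOUS
            )
        else:
            if rng.random() < config.rare_maf_absent_prob:
                maf_global = maf_african = None
            else:
                maf_global = float(rng.uniform(1e-6, 9.9e-5))
                maf_african = float(rng.uniform(1e-6, 9.9e-5))
            sig_name = _choice(rng, config.clinvar_rare_priors)
            genotype = Genotype.HETEROZYGOUS
        sig = _SIG_FROM_NAME[sig_name]
        stars = int(rng.integers(0, 4)) if sig is not ClinvarSignificance.ABSENT else None

        # Sub-threshold scores by construction (PP3 requires >= 2 tools
        # above cut-off; background nulls only ever carry CADD).
        cadd = revel = bayesdel = metarnn = None
        if consequence == "missense_variant":
            if rng.random() < 0.85:
                cadd = float(rng.uniform(0.0, 18.0))
            if rng.random() < 0.85:
                revel = float(rng.uniform(0.0, 0.45))
            if rng.random() < 0.70:
                bayesdel = float(rng.uniform(-0.8, 0.06))
            if rng.random() < 0.70:
                metarnn = float(rng.uniform(0.0, 0.45))
        elif consequence in _NULL_BACKGROUND:
            if rng.random() < 0.70:
                cadd = float(rng.uniform(20.0, 38.0))
        else:
            if rng.random() < 0.40:
                cadd = float(rng.uniform(0.0, 10.0))

        variants.append(
            AnnotatedVariant(
                case_id=case_id,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene_symbol=gene,
                consequence=consequence,
                genotype=genotype,
                maf_global=maf_global,
                maf_african=maf_african,
                clinvar_significance=sig,
                clinvar_stars=stars,
                cadd_phred=cadd,
                revel=revel,
                bayesdel=bayesdel,
                metarnn=metarnn,
                read_depth=int(rng.integers(20, 200)),
            )
        )
    return variants


# ---------------------------------------------------------------------------
# Replication cohort (published cohort table margins)
# ---------------------------------------------------------------------------

#: Enrollment IDs ran NE001-NE035 with three never recruited; the fixture
#: fixes the gaps so that the seven diagnosed IDs and the two consanguineous
#: IDs (NE025, NE035) exist.
_DROPPED_IDS = frozenset({"NE005", "NE013", "NE027"})
_CONSANGUINEOUS_IDS = ("NE025", "NE035")

#: Stratum counts for the 25 undiagnosed cases = published recruit margins
#: minus the seven diagnosed cases' labels.
_NEGATIVE_FILL = {
    "site": [("RMMCH", 11), ("NMCH", 14)],
    "sex": [("female", 13), ("male", 12)],
    "referrer": [("Neonatologist/Paediatrician", 19), ("Geneticist", 6)],
    "ancestry": [("African", 21), ("European", 1), ("Other", 3)],
    "indication": [
        ("Neuromuscular", 1), ("Cardiac", 6), ("Renal", 1),
        ("Multiple congenital anomalies", 8), ("Hepatic", 2),
        ("Developmental", 1), ("Abnormal growth", 1), ("Dysmorphic", 3),
        ("Neurological", 1), ("Gastrointestinal", 1),
    ],
}


def _fill_column(spec: list[tuple[str, int]]) -> list[str]:
    out: list[str] = []
    for value, count in spec:
        out.extend([value] * count)
    return out


def replication_manifest() -> pd.DataFrame:
    """The 32-case cohort manifest with published stratum margins.

    The seven diagnosed cases carry their published labels; the 25
    undiagnosed cases receive labels deterministically so that every
    single-variable margin (site, sex, referrer, ancestry, consanguinity,
    indication) matches the published cohort table exactly. Joint structure
    among the negatives is not constrained by the source and is arbitrary.
    """
    all_ids = [f"NE{i:03d}" for i in range(1, 36) if f"NE{i:03d}" not in _DROPPED_IDS]
    planted = {s.case_id: s for s in REPLICATION_PLANTED_SPECS}
    negative_ids = [cid for cid in all_ids if cid not in planted]

    fills = {key: _fill_column(spec) for key, spec in _NEGATIVE_FILL.items()}
    rows = []
    for cid in all_ids:
        if cid in planted:
            s = planted[cid]
            rows.append(
                dict(case_id=cid, sex=s.sex, site=s.site, referrer=s.referrer,
                     ancestry=s.ancestry, consanguinity="non-consanguineous",
                     indication=s.indication)
            )
        else:
            i = negative_ids.index(cid)
            rows.append(
                dict(
                    case_id=cid,
                    sex=fills["sex"][i],
                    site=fills["site"][i],
                    referrer=fills["referrer"][i],
                    ancestry=fills["ancestry"][i],
                    consanguinity=(
                        "consanguineous" if cid in _CONSANGUINEOUS_IDS
                        else "non-consanguineous"
                    ),
                    indication=fills["indication"][i],
                )
            )
    df = pd.DataFrame(rows)
    df["vcf"] = ["vcfs/" + cid + ".vcf" for cid in df["case_id"]]
    return df


def replication_triage_config() -> TriageConfig:
    """Cascade configuration for the replication cohort.

    Carries the seven curated evidence-code strings (standing in for the
    study's manual curation) and the curators' printed labels so the cascade
    can flag combiner disagreements.
    """
    curated = {
        (s.case_id, s.gene_symbol): s.evidence_code_tokens
        for s in REPLICATION_PLANTED_SPECS
    }
    labels = {
        (s.case_id, s.gene_symbol): s.curated_label
        for s in REPLICATION_PLANTED_SPECS
    }
    return TriageConfig(
        curated_evidence=curated,
        curated_labels=labels,
        lof_genes=LOF_MECHANISM_GENES,
    )


def build_replication_cohort(
    seed: int = 2021, config: SyntheticConfig | None = None
) -> tuple[pd.DataFrame, dict[str, list[AnnotatedVariant]], GenePanel, GenePanel, TriageConfig]:
    """In-memory replication cohort: manifest, per-case variants, panels, config."""
    config = config or SyntheticConfig(seed=seed)
    manifest = replication_manifest()
    nicu = fixture_nicu_panel()
    ddg2p = fixture_ddg2p_panel()
    planted = {s.case_id: s for s in REPLICATION_PLANTED_SPECS}

    variants_by_case: dict[str, list[AnnotatedVariant]] = {}
    for idx, cid in enumerate(manifest["case_id"]):
        background = generate_background(cid, config, seed=seed, case_index=idx)
        if cid in planted:
            background = plant_causative(background, planted[cid], nicu, ddg2p)
        variants_by_case[cid] = background
    return manifest, variants_by_case, nicu, ddg2p, replication_triage_config()


# ---------------------------------------------------------------------------
# VCF serialization of a generated cohort
# ---------------------------------------------------------------------------

_CSQ_FORMAT = (
    "SYMBOL|Consequence|HGVSc|HGVSp|gnomAD_AF|gnomAD_AFR_AF|CLIN_SIG|"
    "ClinVar_STARS|CADD_PHRED|REVEL|BayesDel|MetaRNN"
)

_SIG_TO_VCF = {
    ClinvarSignificance.PATHOGENIC: "pathogenic",
    ClinvarSignificance.LIKELY_PATHOGENIC: "likely_pathogenic",
    ClinvarSignificance.UNCERTAIN: "uncertain_significance",
    ClinvarSignificance.CONFLICTING: "conflicting_interpretations_of_pathogenicity",
    ClinvarSignificance.LIKELY_BENIGN: "likely_benign",
    ClinvarSignificance.BENIGN: "benign",
}

_GT_TO_VCF = {
    Genotype.HETEROZYGOUS: "0/1",
    Genotype.HOMOZYGOUS_ALT: "1/1",
    Genotype.HEMIZYGOUS: "1",
}


def _csq_block(v: AnnotatedVariant) -> str:
    def num(x) -> str:
        return "" if x is None else repr(float(x))

    sig = "" if v.clinvar_significance is ClinvarSignificance.ABSENT else _SIG_TO_VCF[
        v.clinvar_significance
    ]
    stars = "" if v.clinvar_stars is None else str(v.clinvar_stars)
    fields = [
        v.gene_symbol, v.consequence, v.hgvs_c or "", v.hgvs_p or "",
        num(v.maf_global), num(v.maf_african), sig, stars,
        num(v.cadd_phred), num(v.revel), num(v.bayesdel), num(v.metarnn),
    ]
    return "|".join(fields)


def write_case_vcf(path: str | Path, case_id: str, variants: Sequence[AnnotatedVariant]) -> None:
    """Write one case's variants as a single-sample, annotation-carrying VCF 4.2."""
    from .filters import chrom_sort_key

    contigs = sorted({v.chrom for v in variants}, key=chrom_sort_key)
    lines = [
        "##fileformat=VCFv4.2",
        "##reference=GRCh37",
        *[f"##contig=<ID={c}>" for c in contigs],
        f'##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. Format: {_CSQ_FORMAT}">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + case_id,
    ]
    for v in sorted(variants, key=lambda v: (chrom_sort_key(v.chrom), v.pos)):
        dp = "." if v.read_depth is None else str(v.read_depth)
        lines.append(
            "\t".join(
                [
                    v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS",
                    f"CSQ={_csq_block(v)}", "GT:DP",
                    f"{_GT_TO_VCF[v.genotype]}:{dp}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def generate_replication_fixture(
    out_dir: str | Path, seed: int = 2021, config: SyntheticConfig | None = None
) -> dict:
    """Write the canonical replication fixture to disk.

    Produces ``manifest.tsv``, one annotated VCF per case under ``vcfs/``,
    the two fixture panels under ``panels/`` and a ``truth.json`` manifest
    listing every planted causative with its expected tier and curated
    evidence. Regeneration with the same seed is byte-identical.
    """
    out_dir = Path(out_dir)
    (out_dir / "vcfs").mkdir(parents=True, exist_ok=True)
    (out_dir / "panels").mkdir(exist_ok=True)

    manifest, variants_by_case, nicu, ddg2p, triage_config = build_replication_cohort(
        seed=seed, config=config
    )
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    for cid, variants in variants_by_case.items():
        write_case_vcf(out_dir / "vcfs" / f"{cid}.vcf", cid, variants)
    nicu.write(out_dir / "panels" / "nicu_african.tsv")
    ddg2p.write(out_dir / "panels" / "ddg2p.tsv")

    truth = [
        {
            "case_id": s.case_id,
            "gene": s.gene_symbol,
            "hgvs_c": s.hgvs_c,
            "genotype": s.genotype.value,
            "inheritance_mode": s.inheritance_mode,
            "expected_tier": s.expected_tier.value,
            "evidence_codes": s.evidence_code_tokens,
            "curated_label": s.curated_label,
        }
        for s in REPLICATION_PLANTED_SPECS
    ]
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")

    return {
        "manifest": out_dir / "manifest.tsv",
        "vcf_dir": out_dir / "vcfs",
        "panels": {
            "nicu_african": out_dir / "panels" / "nicu_african.tsv",
            "ddg2p": out_dir / "panels" / "ddg2p.tsv",
        },
        "truth": out_dir / "truth.json",
        "triage_config": triage_config,
    }
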