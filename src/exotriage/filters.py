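"""Filtering tiers, variant prioritization and zygosity-consistency rules.

The pipeline applies three sequential retention filters to a case's annotated
variants — membership in a curated neonatal/African virtual panel (tier 1),
prior clinically relevant ClinVar assertions (tier 2), membership in the
DDG2P developmental-disorder panel (tier 3) — and within each tier ranks the
survivors for curation. Every filter is a pure subset operation: it preserves
input order and never mutates variant fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .acmg import EvidenceThresholds
from .errors import ConfigError, DataInconsistencyError
from .gene_panels import GenePanel
from .variant_io import (
    AnnotatedVariant,
    ClinvarSignificance,
    Genotype,
    severity_rank,
)

#: ClinVar categories retained by the tier-2 filter: anything with a prior
#: pathogenic, likely-pathogenic or uncertain assertion, including conflicting
#: interpretations. Benign, likely-benign and unsubmitted variants drop out.
TIER2_RETAINED = frozenset({
    ClinvarSignificance.PATHOGENIC,
    ClinvarSignificance.LIKELY_PATHOGENIC,
    ClinvarSignificance.UNCERTAIN,
    ClinvarSignificance.CONFLICTING,
})

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (_CHROM_ORDER.get(c.upper(), 26), c)


def tier1_panel_filter(
    variants: Sequence[AnnotatedVariant], panel: GenePanel
) -> list[AnnotatedVariant]:
    """Retain variants whose gene is on the tier-1 virtual panel."""
    return [v for v in variants if panel.contains(v.gene_symbol)]


def tier2_clinvar_filter(
    variants: Sequence[AnnotatedVariant],
) -> list[AnnotatedVariant]:
    """Retain variants with a prior P/LP/VUS/conflicting ClinVar assertion."""
    return [v for v in variants if v.clinvar_significance in TIER2_RETAINED]


def tier3_ddg2p_filter(
    variants: Sequence[AnnotatedVariant], panel: GenePanel
) -> list[AnnotatedVariant]:
    """Retain variants whose gene is on the DDG2P panel."""
    return tier1_panel_filter(variants, panel)


def maf_prefilter(
    variants: Sequence[AnnotatedVariant],
    dominant_cutoff: float = 1e-3,
    recessive_cutoff: float = 1e-2,
    founder_genes: Iterable[str] = (),
) -> list[AnnotatedVariant]:
    """Drop variants too common for a Mendelian hypothesis.

    The applicable cutoff follows the observed zygosity: heterozygous calls
    are screened at the dominant-context cutoff, homozygous and hemizygous
    calls at the (laxer) recessive-context cutoff. Genes carrying known
    founder or common disease alleles in African populations are exempt, and
    variants with no population frequency at all are retained (novelty is not
    evidence against).
    """
    for name, cutoff in (("dominant", dominant_cutoff), ("recessive", recessive_cutoff)):
        if not 0.0 <= cutoff <= 1.0:
            raise ConfigError(f"{name}_cutoff={cutoff} outside [0, 1]")
    founders = {g.upper() for g in founder_genes}
    out = []
    for v in variants:
        if v.gene_symbol.upper() in founders:
            out.append(v)
            continue
        maf = v.max_maf
        if maf is None:
            out.append(v)
            continue
        cutoff = dominant_cutoff if v.genotype is Genotype.HETEROZYGOUS else recessive_cutoff
        if maf <= cutoff:
            out.append(v)
    return out


@dataclass(frozen=True)
class PrioritizationKey:
    """Lexicographic ranking key for curation order.

    Variants with prior P/LP ClinVar assertions come first, then more severe
    consequence classes, then rarer alleles (absent MAF ranks as 0: novel
    variants are maximally interesting), then more in-silico tools calling
    the variant deleterious; genomic position breaks remaining ties.
    """

    clinvar_plp_flag: bool
    severity_rank: int
    maf_for_ranking: float
    deleterious_tool_count: int
    position_key: tuple[tuple[int, str], int]

    def sort_tuple(self):
        return (
            not self.clinvar_plp_flag,
            self.severity_rank,
            self.maf_for_ranking,
            -self.deleterious_tool_count,
            self.position_key,
        )


def prioritization_key(
    v: AnnotatedVariant, thresholds: EvidenceThresholds | None = None
) -> PrioritizationKey:
    th = thresholds or EvidenceThresholds()
    n_del = sum(
        1 for tool, s in v.insilico_scores().items() if th.is_deleterious(tool, s)
    )
    return PrioritizationKey(
        clinvar_plp_flag=v.clinvar_significance
        in (ClinvarSignificance.PATHOGENIC, ClinvarSignificance.LIKELY_PATHOGENIC),
        severity_rank=severity_rank(v.consequence),
        maf_for_ranking=v.max_maf or 0.0,
        deleterious_tool_count=n_del,
        position_key=(chrom_sort_key(v.chrom), v.pos),
    )


def prioritize(
    variants: Sequence[AnnotatedVariant],
    thresholds: EvidenceThresholds | None = None,
) -> list[AnnotatedVariant]:
    """Stable sort of the input variants by :class:`PrioritizationKey`."""
    return sorted(variants, key=lambda v: prioritization_key(v, thresholds).sort_tuple())


class ConsistencyVerdict(str, Enum):
    CONSISTENT = "consistent"
    PROVISIONAL_COMPOUND_HET = "provisional_compound_het"
    CARRIER_ONLY = "carrier_only"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


def zygosity_consistent(
    variant: AnnotatedVariant,
    sex: Sex | str,
    inheritance_mode: str,
    gene_cohort_variants: Sequence[AnnotatedVariant] = (),
) -> ConsistencyVerdict:
    """Check whether a genotype can cause disease under an inheritance mode.

    ``gene_cohort_variants`` is the case's other qualifying variants in the
    same gene (after filtering); under autosomal recessive inheritance a
    second heterozygous hit upgrades a carrier call to a provisional,
    unphased compound heterozygote. Proband-only data cannot establish phase,
    hence "provisional".

    Raises :class:`DataInconsistencyError` for a hemizygous call in a female
    case.
    """
    sex = Sex(sex)
    gt = variant.genotype
    if gt is Genotype.HEMIZYGOUS and sex is Sex.FEMALE:
        raise DataInconsistencyError(
            f"hemizygous genotype at {variant.chrom}:{variant.pos} in a female case"
        )

    if inheritance_mode == "autosomal_dominant":
        return ConsistencyVerdict.CONSISTENT
    if inheritance_mode == "autosomal_recessive":
        if gt in (Genotype.HOMOZYGOUS_ALT, Genotype.HEMIZYGOUS):
            return ConsistencyVerdict.CONSISTENT
        others = [
            o
            for o in gene_cohort_variants
            if o is not variant
            and (o.chrom, o.pos, o.ref, o.alt) != (variant.chrom, variant.pos, variant.ref, variant.alt)
            and o.gene_symbol.upper() == variant.gene_symbol.upper()
            and o.genotype is Genotype.HETEROZYGOUS
        ]
        if others:
            return ConsistencyVerdict.PROVISIONAL_COMPOUND_HET
        return ConsistencyVerdict.CARRIER_ONLY
    if inheritance_mode == "x_linked_recessive":
        if gt is Genotype.HEMIZYGOUS:  # male by the check above
            return ConsistencyVerdict.CONSISTENT
        if gt is Genotype.HOMOZYGOUS_ALT:
            return ConsistencyVerdict.CONSISTENT
        return ConsistencyVerdict.CARRIER_ONLY
    raise ConfigError(f"unknown inheritance mode {inheritance_mode!r}")
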