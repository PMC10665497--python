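"""Per-case three-tier sequential triage and cohort orchestration.

Each case's variants pass through tier 1 (NICU/African virtual panel),
tier 2 (prior ClinVar assertions) and tier 3 (DDG2P panel) strictly in that
order. Within a tier the survivors are optionally frequency-prefiltered,
ranked, and the top candidates classified; the first variant reaching
pathogenic or likely pathogenic with an inheritance-consistent genotype is
recorded as causative and stops the cascade — later tiers are not evaluated.
Variants of uncertain significance never make a case positive.

Classification uses curated evidence-code strings when the configuration
supplies them (standing in for the manual-curation step that assigns
family/functional criteria) and falls back to annotation-derived evidence
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .acmg import (
    Classification,
    ClassificationLabel,
    EvidenceCode,
    EvidenceThresholds,
    auto_assign_evidence,
    combine_evidence,
    parse_evidence_string,
)
from .errors import ConfigError, InputError
from .filters import (
    ConsistencyVerdict,
    Sex,
    maf_prefilter,
    prioritize,
    tier1_panel_filter,
    tier2_clinvar_filter,
    tier3_ddg2p_filter,
    zygosity_consistent,
)
from .gene_panels import GenePanel
from .variant_io import AnnotatedVariant, CsqFieldMap, read_annotated_vcf

logger = logging.getLogger(__name__)

POSITIVE_LABELS = (ClassificationLabel.PATHOGENIC, ClassificationLabel.LIKELY_PATHOGENIC)
POSITIVE_VERDICTS = (ConsistencyVerdict.CONSISTENT, ConsistencyVerdict.PROVISIONAL_COMPOUND_HET)


class Tier(str, Enum):
    PANEL = "panel"
    CLINVAR = "clinvar"
    DDG2P = "ddg2p"
    NONE = "none"


#: Known discrepancies between a curated printed label and the points scale;
#: when the combiner disagrees with a curator's label a note is attached.
def _discrepancy_note(expected: str | None, computed: ClassificationLabel) -> str | None:
    if expected is None:
        return None
    if expected.lower().replace(" ", "_") == computed.value:
        return None
    return (
        f"combiner label {computed.value} differs from curated label "
        f"{expected!r} under the points scale"
    )


@dataclass
class TriageConfig:
    """Tunable knobs of the cascade.

    ``curated_evidence`` maps ``(case_id, gene_symbol)`` to a curated
    evidence-code string (``"PM3_strong, PS3, PP3, PP5_supporting"``);
    ``curated_labels`` optionally carries the curator's own classification
    label for discrepancy flagging. ``lof_genes`` lists genes whose disease
    mechanism is loss of function (enables PVS1 auto-assignment);
    ``inheritance_modes`` supplements the modes declared in panel metadata.
    """

    thresholds: EvidenceThresholds = field(default_factory=EvidenceThresholds)
    apply_maf_prefilter: bool = True
    dominant_cutoff: float = 1e-3
    recessive_cutoff: float = 1e-2
    top_n_candidates: int = 25
    clinvar_tier_on_all_variants: bool = True
    curated_evidence: dict[tuple[str, str], str] = field(default_factory=dict)
    curated_labels: dict[tuple[str, str], str] = field(default_factory=dict)
    lof_genes: frozenset[str] = frozenset()
    inheritance_modes: dict[str, str] = field(default_factory=dict)


@dataclass
class CaseResult:
    """Outcome of the cascade for one case."""

    case_id: str
    status: str  # "positive" | "negative"
    tier: Tier
    causative_variant: AnnotatedVariant | None
    classification: Classification | None
    evidence_codes: tuple[EvidenceCode, ...]
    consistency: ConsistencyVerdict | None
    notes: tuple[str, ...] = ()
    tiers_evaluated: tuple[Tier, ...] = ()

    def __post_init__(self) -> None:
        positive = self.status == "positive"
        if positive != (self.causative_variant is not None) or positive != (
            self.tier is not Tier.NONE
        ):
            raise ValueError("inconsistent CaseResult: status/variant/tier disagree")
        if positive:
            assert self.classification is not None
            if self.classification.label not in POSITIVE_LABELS:
                raise ValueError("positive case without a P/LP classification")
            if self.consistency not in POSITIVE_VERDICTS:
                raise ValueError("positive case without genotype consistency")


@dataclass
class CohortResult:
    case_results: list[CaseResult]

    @property
    def n_cases(self) -> int:
        return len(self.case_results)

    @property
    def n_positive(self) -> int:
        return sum(1 for r in self.case_results if r.status == "positive")

    @property
    def yield_percent(self) -> float | None:
        from .reporting import round_percent

        if self.n_cases == 0:
            return None
        return round_percent(100.0 * self.n_positive / self.n_cases)


def _inheritance_modes_for(
    gene: str, panels: Sequence[GenePanel], config: TriageConfig
) -> list[str] | None:
    """Known mode(s) for a gene, or None when no source declares one."""
    gene = gene.upper()
    if gene in config.inheritance_modes:
        return [config.inheritance_modes[gene]]
    for panel in panels:
        if gene in panel.inheritance_modes:
            return [panel.inheritance_modes[gene]]
    return None


_VERDICT_PERMISSIVENESS = {
    ConsistencyVerdict.CONSISTENT: 0,
    ConsistencyVerdict.PROVISIONAL_COMPOUND_HET: 1,
    ConsistencyVerdict.CARRIER_ONLY: 2,
}


def _evaluate_candidate(
    variant: AnnotatedVariant,
    sex: Sex,
    tier_variants: Sequence[AnnotatedVariant],
    panels: Sequence[GenePanel],
    config: TriageConfig,
) -> tuple[Classification, tuple[EvidenceCode, ...], ConsistencyVerdict, list[str]]:
    notes: list[str] = []
    key = (variant.case_id, variant.gene_symbol.upper())
    curated = config.curated_evidence.get(key)
    if curated is not None:
        codes = parse_evidence_string(curated)
    else:
        mechanism = (
            "loss_of_function"
            if variant.gene_symbol.upper() in config.lof_genes
            else "other"
        )
        codes = sorted(
            auto_assign_evidence(variant, mechanism, config.thresholds),
            key=lambda c: c.code_id,
        )
    classification = combine_evidence(codes)
    note = _discrepancy_note(config.curated_labels.get(key), classification.label)
    if note:
        notes.append(note)

    same_gene = [
        v for v in tier_variants if v.gene_symbol.upper() == variant.gene_symbol.upper()
    ]
    modes = _inheritance_modes_for(variant.gene_symbol, panels, config)
    if modes is None:
        # No declared gene-disease mode: evaluate all applicable modes and
        # keep the most permissive verdict, flagged for the curator.
        on_x = variant.chrom.upper().lstrip("CHR") in ("X",)
        candidate_modes = ["autosomal_dominant", "autosomal_recessive"] + (
            ["x_linked_recessive"] if on_x else []
        )
        verdicts = [
            zygosity_consistent(variant, sex, m, same_gene) for m in candidate_modes
        ]
        verdict = min(verdicts, key=lambda v: _VERDICT_PERMISSIVENESS[v])
        notes.append(
            f"no inheritance mode declared for {variant.gene_symbol}; "
            f"most permissive verdict across {candidate_modes} reported"
        )
    else:
        verdict = zygosity_consistent(variant, sex, modes[0], same_gene)
    return classification, tuple(codes), verdict, notes


def run_case(
    case_id: str,
    case_variants: Sequence[AnnotatedVariant],
    sex: Sex | str,
    nicu_panel: GenePanel,
    ddg2p_panel: GenePanel,
    config: TriageConfig | None = None,
) -> CaseResult:
    """Run the three-tier cascade for one case and return its outcome."""
    if nicu_panel is None or ddg2p_panel is None:
        raise ConfigError("both the tier-1 and tier-3 panels must be provided")
    config = config or TriageConfig()
    sex = Sex(sex)

    founder_genes = set(nicu_panel.founder_variant_genes) | set(
        ddg2p_panel.founder_variant_genes
    )
    panels = (nicu_panel, ddg2p_panel)

    tier_plan = (
        (Tier.PANEL, lambda vs: tier1_panel_filter(vs, nicu_panel)),
        (Tier.CLINVAR, tier2_clinvar_filter),
        (Tier.DDG2P, lambda vs: tier3_ddg2p_filter(vs, ddg2p_panel)),
    )

    tiers_evaluated: list[Tier] = []
    for tier, tier_filter in tier_plan:
        tiers_evaluated.append(tier)
        retained = tier_filter(list(case_variants))
        if config.apply_maf_prefilter:
            retained = maf_prefilter(
                retained,
                config.dominant_cutoff,
                config.recessive_cutoff,
                founder_genes,
            )
        ranked = prioritize(retained, config.thresholds)
        for candidate in ranked[: config.top_n_candidates]:
            classification, codes, verdict, notes = _evaluate_candidate(
                candidate, sex, ranked, panels, config
            )
            if classification.label in POSITIVE_LABELS and verdict in POSITIVE_VERDICTS:
                logger.debug(
                    "case %s: causative %s (%s) at tier %s",
                    case_id, candidate.gene_symbol, classification.label.value, tier.value,
                )
                return CaseResult(
                    case_id=case_id,
                    status="positive",
                    tier=tier,
                    causative_variant=candidate,
                    classification=classification,
                    evidence_codes=codes,
                    consistency=verdict,
                    notes=tuple(notes),
                    tiers_evaluated=tuple(tiers_evaluated),
                )
        logger.debug("case %s: no causative variant at tier %s", case_id, tier.value)

    return CaseResult(
        case_id=case_id,
        status="negative",
        tier=Tier.NONE,
        causative_variant=None,
        classification=None,
        evidence_codes=(),
        consistency=None,
        notes=(),
        tiers_evaluated=tuple(tiers_evaluated),
    )


def run_cohort(
    manifest: pd.DataFrame,
    variants_by_case: Mapping[str, Sequence[AnnotatedVariant]],
    nicu_panel: GenePanel,
    ddg2p_panel: GenePanel,
    config: TriageConfig | None = None,
) -> CohortResult:
    """Run the cascade over every case in a cohort manifest.

    The manifest must carry ``case_id`` and ``sex`` columns; each case_id
    must have an entry in ``variants_by_case``.
    """
    for col in ("case_id", "sex"):
        if col not in manifest.columns:
            raise InputError(f"cohort manifest lacks required column {col!r}")
    missing = [c for c in manifest["case_id"] if c not in variants_by_case]
    if missing:
        raise InputError(f"no variant set for manifest case(s): {missing}")

    results = [
        run_case(
            row.case_id,
            variants_by_case[row.case_id],
            row.sex,
            nicu_panel,
            ddg2p_panel,
            config,
        )
        for row in manifest.itertuples()
    ]
    cohort = CohortResult(results)
    if cohort.n_cases == 0:
        logger.warning("empty cohort: diagnostic yield is undefined")
    return cohort


def run_cohort_from_files(
    manifest_path: str | Path,
    nicu_panel: GenePanel,
    ddg2p_panel: GenePanel,
    config: TriageConfig | None = None,
    csq_map: CsqFieldMap | None = None,
) -> tuple[CohortResult, pd.DataFrame]:
    """Read a manifest TSV (with a ``vcf`` path column) and run the cohort."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str)
    if "vcf" not in manifest.columns:
        raise InputError(f"{manifest_path}: manifest lacks a 'vcf' column")
    variants_by_case = {
        row.case_id: read_annotated_vcf(
            manifest_path.parent / row.vcf, csq_map, case_id=row.case_id
        )
        for row in manifest.itertuples()
    }
    result = run_cohort(manifest, variants_by_case, nicu_panel, ddg2p_panel, config)
    return result, manifest
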