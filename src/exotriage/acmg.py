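"""ACMG/AMP evidence codes, strength modifiers and the points-based combiner.

Curators routinely apply an evidence criterion at a strength other than its
default (e.g. PM3 applied at strong, PVS1 demoted to strong). The original
2015 rule-combination table cannot express such modified sets, so this engine
combines evidence on the Bayesian points scale: supporting / moderate /
strong / very strong contribute 1 / 2 / 4 / 8 points (negated for
benign-direction codes; the stand-alone benign criterion BA1 counts -8), and
the summed total maps to the five-tier classification:

    >= 10        pathogenic
    6 .. 9       likely_pathogenic
    0 .. 5       uncertain_significance
    -6 .. -1     likely_benign
    <= -7        benign

The module also auto-assigns the small subset of criteria that are derivable
from variant annotations alone (PVS1, PM2_supporting, PP3, PP5_supporting,
BP4, BA1). Family-, functional- and hotspot-based criteria (PS2, PS3, PS4,
PM1, PM3, PM5, PP1, PP2, ...) require curation and are never auto-assigned;
they enter the pipeline through parsed curated code strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, TYPE_CHECKING

from .errors import EvidenceParseError

if TYPE_CHECKING:  # pragma: no cover
    from .variant_io import AnnotatedVariant


class Strength(str, Enum):
    SUPPORTING = "supporting"
    MODERATE = "moderate"
    STRONG = "strong"
    VERY_STRONG = "very_strong"
    STAND_ALONE_BENIGN = "stand_alone_benign"


#: Points magnitude per applied strength.
_STRENGTH_POINTS = {
    Strength.SUPPORTING: 1,
    Strength.MODERATE: 2,
    Strength.STRONG: 4,
    Strength.VERY_STRONG: 8,
    Strength.STAND_ALONE_BENIGN: 8,
}

#: Base (default) strength per code family prefix.
_BASE_STRENGTH = {
    "PVS": Strength.VERY_STRONG,
    "PS": Strength.STRONG,
    "PM": Strength.MODERATE,
    "PP": Strength.SUPPORTING,
    "BA": Strength.STAND_ALONE_BENIGN,
    "BS": Strength.STRONG,
    "BP": Strength.SUPPORTING,
}

VALID_CODE_IDS = frozenset(
    ["PVS1", "BA1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)

_MODIFIER_ALIASES = {
    "supporting": Strength.SUPPORTING,
    "moderate": Strength.MODERATE,
    "strong": Strength.STRONG,
    "verystrong": Strength.VERY_STRONG,
    "standalone": Strength.STAND_ALONE_BENIGN,
    "standalonebenign": Strength.STAND_ALONE_BENIGN,
}

_TOKEN_RE = re.compile(r"^([A-Za-z]+)(\d+)(?:[_\s]+(.+))?$")


@dataclass(frozen=True)
class EvidenceCode:
    """One ACMG/AMP criterion with its default and applied strengths.

    ``explicit_modifier`` records whether the source token spelled the
    strength out (curators write ``PP5_supporting`` for emphasis even though
    supporting is PP5's default); it affects only formatting, never identity
    or points.
    """

    code_id: str
    applied_strength: Strength
    explicit_modifier: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.code_id not in VALID_CODE_IDS:
            raise EvidenceParseError(f"unknown evidence code {self.code_id!r}")

    @property
    def family(self) -> str:
        return re.match(r"[A-Z]+", self.code_id).group(0)

    @property
    def base_strength(self) -> Strength:
        return _BASE_STRENGTH[self.family]

    @property
    def is_benign_direction(self) -> bool:
        return self.family in ("BA", "BS", "BP")

    def __str__(self) -> str:
        if self.applied_strength is self.base_strength and not self.explicit_modifier:
            return self.code_id
        label = self.applied_strength.value.replace("_", " ")
        return f"{self.code_id}_{label}"


def code(code_id: str, applied: Strength | None = None) -> EvidenceCode:
    """Construct an EvidenceCode, defaulting to the code's base strength."""
    code_id = code_id.upper()
    if code_id not in VALID_CODE_IDS:
        raise EvidenceParseError(f"unknown evidence code {code_id!r}")
    base = _BASE_STRENGTH[re.match(r"[A-Z]+", code_id).group(0)]
    return EvidenceCode(code_id, applied if applied is not None else base)


def parse_evidence_code(token: str) -> EvidenceCode:
    """Parse one code token, e.g. ``PM3_strong`` or ``PS2_very strong``.

    Tolerant of case and of underscores vs spaces inside the modifier;
    an absent modifier means the code applies at its default strength.
    """
    token = token.strip()
    if not token:
        raise EvidenceParseError("empty evidence-code token")
    m = _TOKEN_RE.match(token)
    if not m:
        raise EvidenceParseError(f"cannot parse evidence code {token!r}")
    code_id = (m.group(1) + m.group(2)).upper()
    if code_id not in VALID_CODE_IDS:
        raise EvidenceParseError(f"unknown evidence code in token {token!r}")
    modifier = m.group(3)
    if modifier is None:
        return code(code_id)
    key = re.sub(r"[_\s\-]", "", modifier).lower()
    strength = _MODIFIER_ALIASES.get(key)
    if strength is None:
        raise EvidenceParseError(f"unknown strength modifier in token {token!r}")
    return EvidenceCode(code_id, strength, explicit_modifier=True)


def parse_evidence_string(text: str) -> list[EvidenceCode]:
    """Parse a comma-separated curated code string (``PM3_strong, PS3, PP3``)."""
    return [parse_evidence_code(tok) for tok in text.split(",") if tok.strip()]


def format_evidence_string(codes: Iterable[EvidenceCode]) -> str:
    return ", ".join(str(c) for c in codes)


def points(ev: EvidenceCode) -> int:
    """Signed point value of one applied evidence code."""
    magnitude = _STRENGTH_POINTS[ev.applied_strength]
    return -magnitude if ev.is_benign_direction else magnitude


class ClassificationLabel(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN_SIGNIFICANCE = "uncertain_significance"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


@dataclass(frozen=True)
class Classification:
    label: ClassificationLabel
    points: int


def label_for_points(total: int) -> ClassificationLabel:
    if total >= 10:
        return ClassificationLabel.PATHOGENIC
    if total >= 6:
        return ClassificationLabel.LIKELY_PATHOGENIC
    if total >= 0:
        return ClassificationLabel.UNCERTAIN_SIGNIFICANCE
    if total >= -6:
        return ClassificationLabel.LIKELY_BENIGN
    return ClassificationLabel.BENIGN


def combine_evidence(codes: Iterable[EvidenceCode]) -> Classification:
    """Sum applied evidence points and map to the five-tier classification.

    Raises ``ValueError`` if the same criterion appears twice.
    """
    codes = list(codes)
    ids = [c.code_id for c in codes]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate evidence code(s): {dups}")
    total = sum(points(c) for c in codes)
    return Classification(label_for_points(total), total)


# ---------------------------------------------------------------------------
# Annotation-derived evidence assignment
# ---------------------------------------------------------------------------

#: Consequence terms treated as predicted loss-of-function (null) for PVS1.
NULL_CONSEQUENCES = frozenset({
    "stop_gained", "frameshift_variant",
    "splice_acceptor_variant", "splice_donor_variant", "start_lost",
})


@dataclass(frozen=True)
class EvidenceThresholds:
    """Config for the annotation-derived evidence rules.

    Deleteriousness cut-offs follow each tool's conventional operating point;
    all are overridable. ``rare_maf`` bounds PM2_supporting; ``ba1_maf`` is
    the stand-alone common-variant threshold.
    """

    rare_maf: float = 1e-4
    ba1_maf: float = 0.05
    cadd_phred: float = 20.0
    revel: float = 0.5
    bayesdel: float = 0.0692
    metarnn: float = 0.5
    min_clinvar_stars_pp5: int = 1
    min_tools_for_pp3: int = 2

    def is_deleterious(self, tool: str, score: float) -> bool:
        return score >= getattr(self, tool)


def auto_assign_evidence(
    variant: "AnnotatedVariant",
    gene_mechanism: str = "other",
    thresholds: EvidenceThresholds | None = None,
) -> set[EvidenceCode]:
    """Assign the minimal annotation-derivable evidence set for one variant.

    Rules (each skipped when its annotations are absent):

    * PVS1 — null consequence in a gene whose disease mechanism is
      loss of function;
    * PM2_supporting — every available population MAF below ``rare_maf``
      (all-absent also qualifies: never observed);
    * PP3 / BP4 — majority of available in-silico tools predict deleterious /
      benign, with at least ``min_tools_for_pp3`` tools available;
    * PP5_supporting — prior pathogenic or likely-pathogenic ClinVar
      assertion with at least one review star (guards against circular
      evidence from unreviewed submissions);
    * BA1 — any population MAF at or above ``ba1_maf``.
    """
    from .variant_io import ClinvarSignificance  # local import avoids a cycle

    th = thresholds or EvidenceThresholds()
    assigned: set[EvidenceCode] = set()

    base_consequences = {t.strip() for t in variant.consequence.split("&")}
    if gene_mechanism == "loss_of_function" and base_consequences & NULL_CONSEQUENCES:
        assigned.add(code("PVS1"))

    mafs = [m for m in (variant.maf_global, variant.maf_african) if m is not None]
    if all(m < th.rare_maf for m in mafs):  # vacuously true when all absent
        assigned.add(code("PM2", Strength.SUPPORTING))
    if any(m >= th.ba1_maf for m in mafs):
        assigned.discard(code("PM2", Strength.SUPPORTING))
        assigned.add(code("BA1"))

    scores = variant.insilico_scores()
    if len(scores) >= th.min_tools_for_pp3:
        n_del = sum(1 for tool, s in scores.items() if th.is_deleterious(tool, s))
        if n_del > len(scores) / 2:
            assigned.add(code("PP3"))
        elif (len(scores) - n_del) > len(scores) / 2:
            assigned.add(code("BP4"))

    if (
        variant.clinvar_significance
        in (ClinvarSignificance.PATHOGENIC, ClinvarSignificance.LIKELY_PATHOGENIC)
        and (variant.clinvar_stars or 0) >= th.min_clinvar_stars_pp5
    ):
        # curated convention spells the strength out on PP5
        assigned.add(EvidenceCode("PP5", Strength.SUPPORTING, explicit_modifier=True))

    return assigned
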