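"""Reading annotated single-sample VCFs into the pipeline's variant model.

The pipeline consumes exomes that have already been annotated upstream with a
VEP-style pipe-delimited consequence field (``CSQ`` by default). Each VCF
record is split per alternate allele; only alleles the proband actually
carries become :class:`AnnotatedVariant` objects. Indel alleles are reduced to
minimal representation so that gene-panel and ClinVar matching is stable
across annotation sources.

Coordinates follow the 1-based VCF convention on GRCh37. Missing annotation
subfields stay *absent* (``None``); they are never imputed to zero.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .errors import DataInconsistencyError, InputError, UnsupportedInputError

logger = logging.getLogger(__name__)

MISSING_TOKEN = "."

#: Contigs on which a single-copy (hemizygous) genotype is legitimate.
DEFAULT_HAPLOID_CONTIGS = frozenset({"X", "Y", "chrX", "chrY"})


class Genotype(str, Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS_ALT = "homozygous_alt"
    HEMIZYGOUS = "hemizygous"


class ClinvarSignificance(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain"
    CONFLICTING = "conflicting"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    ABSENT = "absent"


def normalize_clinvar_significance(raw: str | None) -> ClinvarSignificance:
    """Map a free-text ClinVar assertion to the pipeline's enumeration.

    Normalization is case-insensitive. Any value mentioning conflicting
    interpretations maps to ``conflicting``. Joint assertions such as
    ``Pathogenic/Likely_pathogenic`` map to the weaker member of the pair.
    """
    if raw is None or raw.strip() in ("", MISSING_TOKEN):
        return ClinvarSignificance.ABSENT
    s = raw.strip().lower().replace(" ", "_")
    if "conflicting" in s:
        return ClinvarSignificance.CONFLICTING
    if "likely_pathogenic" in s:
        return ClinvarSignificance.LIKELY_PATHOGENIC
    if "pathogenic" in s:
        return ClinvarSignificance.PATHOGENIC
    if "likely_benign" in s:
        return ClinvarSignificance.LIKELY_BENIGN
    if "benign" in s:
        return ClinvarSignificance.BENIGN
    if "uncertain" in s or s == "vus":
        return ClinvarSignificance.UNCERTAIN
    return ClinvarSignificance.ABSENT


@dataclass(frozen=True)
class AnnotatedVariant:
    """One alternate-allele call in one case, with its annotations.

    MAF fields are population allele frequencies in [0, 1]; in-silico scores
    keep their native scales (CADD is PHRED-like and unbounded above, REVEL
    and MetaRNN live in [0, 1], BayesDel is signed). ``None`` means the
    annotation was absent upstream.
    """

    case_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_symbol: str
    consequence: str
    genotype: Genotype
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    maf_global: float | None = None
    maf_african: float | None = None
    clinvar_significance: ClinvarSignificance = ClinvarSignificance.ABSENT
    clinvar_stars: int | None = None
    cadd_phred: float | None = None
    revel: float | None = None
    bayesdel: float | None = None
    metarnn: float | None = None
    read_depth: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for name in ("maf_global", "maf_african"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.clinvar_stars is not None:
            if self.clinvar_significance is ClinvarSignificance.ABSENT:
                raise ValueError("clinvar_stars present without a ClinVar assertion")
            if not 0 <= self.clinvar_stars <= 4:
                raise ValueError(f"clinvar_stars={self.clinvar_stars} outside 0-4")
        if self.genotype is Genotype.HEMIZYGOUS and _strip_chr(self.chrom) not in ("X", "Y"):
            raise ValueError(f"hemizygous genotype on diploid contig {self.chrom}")

    @property
    def max_maf(self) -> float | None:
        """Maximum across available population frequencies; None if all absent."""
        mafs = [m for m in (self.maf_global, self.maf_african) if m is not None]
        return max(mafs) if mafs else None

    def insilico_scores(self) -> dict[str, float]:
        """Available in-silico predictor scores by tool name."""
        out = {}
        for tool in ("cadd_phred", "revel", "bayesdel", "metarnn"):
            v = getattr(self, tool)
            if v is not None:
                out[tool] = v
        return out


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


# ---------------------------------------------------------------------------
# Annotation dialect
# ---------------------------------------------------------------------------

#: Semantic roles the pipeline understands inside the pipe-delimited block.
CSQ_ROLES = (
    "symbol", "consequence", "hgvs_c", "hgvs_p", "maf_global", "maf_african",
    "clin_sig", "clinvar_stars", "cadd_phred", "revel", "bayesdel", "metarnn",
    "canonical",
)

_DEFAULT_FIELDS = [
    "SYMBOL", "Consequence", "HGVSc", "HGVSp", "gnomAD_AF", "gnomAD_AFR_AF",
    "CLIN_SIG", "ClinVar_STARS", "CADD_PHRED", "REVEL", "BayesDel", "MetaRNN",
]
_DEFAULT_ROLES = dict(zip(CSQ_ROLES[:12], _DEFAULT_FIELDS))


@dataclass(frozen=True)
class CsqFieldMap:
    """Dialect adapter for the VEP-style annotation INFO field.

    ``field_names`` is the ordered list of pipe-delimited subfield names as
    declared in the VCF header; ``roles`` maps each semantic role the pipeline
    uses to the subfield name that carries it. Only ``symbol`` and
    ``consequence`` are required; every other role is optional and missing
    roles simply leave the corresponding annotation absent.
    """

    annotation_key: str = "CSQ"
    field_names: tuple[str, ...] = tuple(_DEFAULT_FIELDS)
    roles: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_ROLES))

    def __post_init__(self) -> None:
        if not self.field_names:
            raise ValueError("field_names must be non-empty")
        if len(set(self.field_names)) != len(self.field_names):
            raise ValueError("field_names must be unique")
        for role in ("symbol", "consequence"):
            if role not in self.roles:
                raise ValueError(f"required role {role!r} missing from roles")
        for role, name in self.roles.items():
            if role not in CSQ_ROLES:
                raise ValueError(f"unknown role {role!r}")
            if name not in self.field_names:
                raise ValueError(f"role {role!r} maps to undeclared field {name!r}")

    def parse_block(self, block: str) -> dict[str, str]:
        """Split one pipe-delimited transcript block into role -> raw text."""
        parts = block.split("|")
        by_name = dict(zip(self.field_names, parts))
        out = {}
        for role, name in self.roles.items():
            raw = by_name.get(name, "")
            if raw not in ("", MISSING_TOKEN):
                out[role] = raw
        return out


# ---------------------------------------------------------------------------
# Consequence severity (shared with the prioritization module)
# ---------------------------------------------------------------------------

#: Fixed severity ordering, most severe first. Terms are Sequence Ontology.
CONSEQUENCE_SEVERITY: tuple[str, ...] = (
    "stop_gained",
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "start_lost",
    "stop_lost",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "splice_region_variant",
    "synonymous_variant",
)
_SEVERITY_RANK = {term: i for i, term in enumerate(CONSEQUENCE_SEVERITY)}
#: Rank assigned to any term not in the table ("other": intronic, UTR, ...).
OTHER_SEVERITY_RANK = len(CONSEQUENCE_SEVERITY)


def severity_rank(consequence: str) -> int:
    """Rank of a consequence term (lower = more severe).

    Compound VEP terms joined with ``&`` rank by their most severe component.
    """
    ranks = [
        _SEVERITY_RANK.get(term.strip(), OTHER_SEVERITY_RANK)
        for term in consequence.split("&")
    ]
    return min(ranks) if ranks else OTHER_SEVERITY_RANK


def select_primary_consequence(blocks: Sequence[dict[str, str]]) -> dict[str, str]:
    """Pick one annotation block per variant for prioritization.

    Chooses the block with the most severe consequence term; ties break on a
    truthy ``canonical`` flag, then on first occurrence.
    """
    if not blocks:
        raise ValueError("select_primary_consequence requires >= 1 annotation block")

    def key(item: tuple[int, dict[str, str]]) -> tuple[int, int, int]:
        i, block = item
        rank = severity_rank(block.get("consequence", ""))
        canonical = 0 if block.get("canonical", "").upper() in ("YES", "1", "TRUE") else 1
        return (rank, canonical, i)

    return min(enumerate(blocks), key=key)[1]


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


def _minimal_representation(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then prefix so indels match representation-stably."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _float_or_none(raw: str | None) -> float | None:
    if raw is None:
        return None
    try:
        return float(raw)
    except ValueError:
        return None


def _genotype_for_alt(
    alleles: tuple[int | None, ...], alt_index: int, chrom: str,
    haploid_contigs: frozenset[str],
) -> Genotype | None:
    """Re-express a genotype against one alt allele; None if not carried."""
    called = [a for a in alleles if a is not None]
    n_alt = sum(1 for a in called if a == alt_index)
    if n_alt == 0:
        return None
    if len(called) == 1:
        if chrom not in haploid_contigs and _strip_chr(chrom) not in ("X", "Y"):
            raise DataInconsistencyError(
                f"single-allele genotype on diploid contig {chrom}"
            )
        return Genotype.HEMIZYGOUS
    if n_alt == len(called):
        return Genotype.HOMOZYGOUS_ALT
    return Genotype.HETEROZYGOUS


def read_annotated_vcf(
    path: str | Path,
    csq_map: CsqFieldMap | None = None,
    case_id: str | None = None,
    haploid_contigs: frozenset[str] = DEFAULT_HAPLOID_CONTIGS,
) -> list[AnnotatedVariant]:
    """Read a single-sample annotated VCF into AnnotatedVariant objects.

    One variant is emitted per (record, alt allele) pair that the sample
    carries; multi-allelic records are split and the genotype re-expressed
    against each alt. Records without the annotation INFO key are skipped
    with a warning. Missing numeric subfields remain absent, never zero.

    Raises
    ------
    InputError
        If the file is unreadable, not valid VCF, or lacks genotypes.
    UnsupportedInputError
        If the VCF has more than one sample column.
    """
    csq_map = csq_map or CsqFieldMap()
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read VCF {path}: {exc}") from exc

    with vcf:
        samples = list(vcf.header.samples)
        if len(samples) > 1:
            raise UnsupportedInputError(
                f"{path}: expected a single-sample VCF, found {len(samples)} samples"
            )
        if not samples:
            raise InputError(f"{path}: VCF has no sample column (no genotypes)")
        sample = samples[0]
        if case_id is None:
            case_id = sample

        variants: list[AnnotatedVariant] = []
        n_skipped = 0
        for rec in vcf:
            raw_csq = rec.info.get(csq_map.annotation_key)
            if raw_csq is None:
                n_skipped += 1
                continue
            if isinstance(raw_csq, str):
                raw_csq = (raw_csq,)
            blocks = [csq_map.parse_block(b) for b in raw_csq]

            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or all(a is None for a in gt):
                raise InputError(f"{path}: record {rec.chrom}:{rec.pos} lacks GT")
            depth = call.get("DP")

            for alt_index, alt in enumerate(rec.alts or (), start=1):
                genotype = _genotype_for_alt(gt, alt_index, rec.chrom, haploid_contigs)
                if genotype is None:
                    continue
                # Annotation blocks for this alt (VEP puts ALLELE_NUM or the
                # allele itself first; our dialect is one block set per record,
                # so all blocks apply to every alt).
                primary = select_primary_consequence(blocks)
                pos, ref, alt_min = _minimal_representation(rec.pos, rec.ref, alt)
                stars_raw = primary.get("clinvar_stars")
                sig = normalize_clinvar_significance(primary.get("clin_sig"))
                stars = None
                if stars_raw is not None and sig is not ClinvarSignificance.ABSENT:
                    try:
                        stars = int(float(stars_raw))
                    except ValueError:
                        stars = None
                variants.append(
                    AnnotatedVariant(
                        case_id=case_id,
                        chrom=rec.chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt_min,
                        gene_symbol=primary.get("symbol", ""),
                        consequence=primary.get("consequence", ""),
                        genotype=genotype,
                        hgvs_c=primary.get("hgvs_c"),
                        hgvs_p=primary.get("hgvs_p"),
                        maf_global=_float_or_none(primary.get("maf_global")),
                        maf_african=_float_or_none(primary.get("maf_african")),
                        clinvar_significance=sig,
                        clinvar_stars=stars,
                        cadd_phred=_float_or_none(primary.get("cadd_phred")),
                        revel=_float_or_none(primary.get("revel")),
                        bayesdel=_float_or_none(primary.get("bayesdel")),
                        metarnn=_float_or_none(primary.get("metarnn")),
                        read_depth=int(depth) if depth is not None else None,
                    )
                )
        if n_skipped:
            logger.warning(
                "%s: skipped %d record(s) without %s annotation",
                path, n_skipped, csq_map.annotation_key,
            )
    return variants


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

TABLE_COLUMNS = (
    "case_id", "chrom", "pos", "ref", "alt", "gene_symbol", "consequence",
    "genotype", "hgvs_c", "hgvs_p", "maf_global", "maf_african",
    "clinvar_significance", "clinvar_stars", "cadd_phred", "revel",
    "bayesdel", "metarnn", "read_depth",
)


def _cell(value) -> str:
    if value is None:
        return MISSING_TOKEN
    if isinstance(value, Enum):
        return value.value
    return repr(value) if isinstance(value, float) else str(value)


def write_variant_table(variants: Iterable[AnnotatedVariant], path: str | Path) -> int:
    """Write a TSV variant table; returns the number of data rows written.

    Absent values serialize as ``.``; re-reading with
    :func:`read_variant_table` reproduces all fields exactly.
    """
    n = 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TABLE_COLUMNS)
        for v in variants:
            writer.writerow([_cell(getattr(v, col)) for col in TABLE_COLUMNS])
            n += 1
    return n


def read_variant_table(path: str | Path) -> list[AnnotatedVariant]:
    """Inverse of :func:`write_variant_table`."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            def get(col: str):
                val = row[col]
                return None if val == MISSING_TOKEN else val

            out.append(
                AnnotatedVariant(
                    case_id=row["case_id"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    gene_symbol=row["gene_symbol"],
                    consequence=row["consequence"],
                    genotype=Genotype(row["genotype"]),
                    hgvs_c=get("hgvs_c"),
                    hgvs_p=get("hgvs_p"),
                    maf_global=_float_or_none(get("maf_global")),
                    maf_african=_float_or_none(get("maf_african")),
                    clinvar_significance=ClinvarSignificance(row["clinvar_significance"]),
                    clinvar_stars=int(row["clinvar_stars"]) if get("clinvar_stars") else None,
                    cadd_phred=_float_or_none(get("cadd_phred")),
                    revel=_float_or_none(get("revel")),
                    bayesdel=_float_or_none(get("bayesdel")),
                    metarnn=_float_or_none(get("metarnn")),
                    read_depth=int(row["read_depth"]) if get("read_depth") else None,
                )
            )
    return out
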