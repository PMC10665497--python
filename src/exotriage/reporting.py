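"""Diagnostic yield, stratified cohort summaries and per-case reports.

Percentages are rounded to one decimal with round-half-up throughout, the
convention used in clinical yield reporting (7/32 prints as 21.9, 6/17 as
35.3). Case reports follow the study's reporting rule: only pathogenic and
likely-pathogenic findings are returned; variants of uncertain significance
and incidental findings never appear in a report body.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .acmg import format_evidence_string
from .cascade import CaseResult, CohortResult, Tier
from .errors import ConfigError, UndefinedYieldError

TIER_LABELS = {
    Tier.PANEL: "NICU/African Panel",
    Tier.CLINVAR: "ClinVar Filter",
    Tier.DDG2P: "DDG2P Panel",
    Tier.NONE: "—",
}


def round_percent(value: float) -> float:
    """One-decimal round-half-up, matching printed clinical yield tables."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def diagnostic_yield(result: CohortResult) -> float:
    """Cohort diagnostic yield as a percentage (one decimal)."""
    if result.n_cases == 0:
        raise UndefinedYieldError("diagnostic yield undefined for an empty cohort")
    return round_percent(100.0 * result.n_positive / result.n_cases)


@dataclass(frozen=True)
class StratumSummary:
    """One row of a stratified yield table (e.g. ``site=RMMCH``)."""

    stratum_key: str
    n_recruited: int
    percent_of_cohort: float
    n_positive: int
    percent_positive: float


def stratified_summary(
    result: CohortResult,
    manifest: pd.DataFrame,
    keys: Sequence[str],
) -> list[StratumSummary]:
    """Summarize recruit counts and positive yield per stratum.

    One :class:`StratumSummary` per observed level of each stratification
    key (manifest column). Levels with zero positives are reported with 0 /
    0.0, not omitted. Within each key, recruit counts sum to the cohort
    total and positive counts to the cohort's positives.
    """
    if "case_id" not in manifest.columns:
        raise ConfigError("manifest lacks a case_id column")
    known = set(manifest["case_id"])
    missing = [r.case_id for r in result.case_results if r.case_id not in known]
    if missing:
        raise ConfigError(f"manifest does not cover case(s): {missing}")
    positive_ids = {r.case_id for r in result.case_results if r.status == "positive"}
    n_total = result.n_cases

    summaries: list[StratumSummary] = []
    for key in keys:
        if key not in manifest.columns:
            raise ConfigError(f"unknown stratification field {key!r}")
        for level, group in manifest.groupby(key, sort=True):
            n = len(group)
            n_pos = sum(1 for cid in group["case_id"] if cid in positive_ids)
            summaries.append(
                StratumSummary(
                    stratum_key=f"{key}={level}",
                    n_recruited=n,
                    percent_of_cohort=round_percent(100.0 * n / n_total) if n_total else 0.0,
                    n_positive=n_pos,
                    percent_positive=round_percent(100.0 * n_pos / n) if n else 0.0,
                )
            )
    return summaries


def summary_table(summaries: Sequence[StratumSummary]) -> pd.DataFrame:
    """Stratified summaries as a four-column DataFrame mirroring a yield table."""
    return pd.DataFrame(
        {
            "stratum": [s.stratum_key for s in summaries],
            "n_recruited": [s.n_recruited for s in summaries],
            "percent_of_cohort": [s.percent_of_cohort for s in summaries],
            "n_positive": [s.n_positive for s in summaries],
            "percent_positive": [s.percent_positive for s in summaries],
        }
    )


def case_report(result: CaseResult) -> dict:
    """Machine-readable clinical-style report for one case.

    Positive reports carry the gene, HGVS notation, zygosity, classification,
    the curated-format evidence string, the discovery tier and any notes.
    Negative reports state that no reportable variant was found across all
    three filtering strategies; VUS candidates are deliberately absent.
    """
    report: dict = {"case_id": result.case_id, "result": result.status}
    if result.status == "positive":
        v = result.causative_variant
        report["finding"] = {
            "gene": v.gene_symbol,
            "hgvs_c": v.hgvs_c,
            "hgvs_p": v.hgvs_p,
            "zygosity": v.genotype.value,
            "classification": result.classification.label.value,
            "evidence_codes": format_evidence_string(result.evidence_codes),
            "filtering_strategy": TIER_LABELS[result.tier],
            "consistency": result.consistency.value,
            "read_depth": v.read_depth,
        }
        if result.notes:
            report["notes"] = list(result.notes)
    else:
        report["statement"] = (
            "No pathogenic or likely pathogenic variant consistent with the "
            "reported phenotype was identified across the three filtering "
            "strategies (virtual gene panel, ClinVar, DDG2P)."
        )
    return report


def render_case_report(result: CaseResult) -> str:
    """Human-readable rendering of :func:`case_report`."""
    rep = case_report(result)
    lines = [f"Case {rep['case_id']}: {rep['result'].upper()}"]
    if rep["result"] == "positive":
        f = rep["finding"]
        lines += [
            f"  Gene:            {f['gene']}",
            f"  Variant:         {f['hgvs_c'] or '—'} ({f['hgvs_p'] or '—'})",
            f"  Zygosity:        {f['zygosity']}",
            f"  Classification:  {f['classification']}",
            f"  Evidence codes:  {f['evidence_codes']}",
            f"  Strategy:        {f['filtering_strategy']}",
        ]
        for note in rep.get("notes", []):
            lines.append(f"  Note: {note}")
    else:
        lines.append(f"  {rep['statement']}")
    return "\n".join(lines)
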