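# Methods

## Scope and data model

`exotriage` operates downstream of alignment, variant calling and VEP-style
annotation: its input is a single-sample VCF 4.x whose records carry a
pipe-delimited consequence INFO field (`CSQ` by default; the dialect is
configurable through `CsqFieldMap` because VEP field sets vary). Coordinates
are 1-based VCF convention on GRCh37; no liftover is provided. Each
(record, alt-allele) pair the proband carries becomes one
`AnnotatedVariant`; multi-allelic records are split per alt with the
genotype re-expressed against that alt, and indel alleles are reduced to
minimal representation (shared suffix then prefix trimmed) so gene-panel and
ClinVar matching is stable across representations. Absent annotations stay
absent (`None`) through all I/O — a missing REVEL score is never 0.

Genotype mapping: `0/1` → heterozygous, `1/1` → homozygous_alt, and a
single-allele call (`1`) on a sex chromosome → hemizygous. Case sex comes
from the cohort manifest, never from the VCF; a hemizygous call in a female
case is a hard data-inconsistency error.

ClinVar assertions are normalized case-insensitively; any string mentioning
conflicting interpretations maps to `conflicting`, and joint
`Pathogenic/Likely_pathogenic` assertions map to the weaker member
(`likely_pathogenic`) — the choice is behaviourally inert, since both labels
are retained at tier 2, both set the prioritization flag and both qualify
for PP5.

## The cascade

Tiers run strictly in order — virtual panel, ClinVar retention, DDG2P —
and each tier applies: retention filter → optional frequency prefilter →
prioritization → classification of the top candidates (default 25, a bound
on curation work) in rank order. The first candidate that classifies
pathogenic or likely pathogenic *and* passes the zygosity-consistency check
is recorded as causative with its tier, and the cascade stops; the
per-case result keeps an execution trace (`tiers_evaluated`) so the stop
rule is observable. Variants of uncertain significance can never make a
case positive, matching the workflow's reporting rule (VUS and incidental
findings are not returned).

The tier-2 filter is applied to the case's *full* variant set, not the
tier-1 survivors: the retention rule is an independent strategy, not a
refinement (a config flag exists because the alternative reading is
defensible).

### Prioritization

Lexicographic key: prior P/LP ClinVar assertion first; then consequence
severity under a fixed documented ordering (stop_gained > frameshift >
canonical splice > start/stop lost > inframe indel > missense > splice
region > synonymous > other; compound `&`-joined terms rank by their most
severe component); then maximum available population MAF ascending with
absent ranked 0 (novel variants are maximally interesting); then the count
of in-silico tools calling the variant deleterious, descending; genomic
position breaks remaining ties. The sort is stable and total.

### Frequency prefilter

Optional (default on). A variant is dropped when its maximum available MAF
exceeds the cutoff applicable to its zygosity: 0.001 for heterozygous
(dominant-context) calls, 0.01 for homozygous/hemizygous (recessive-context)
calls. Genes flagged as carrying African founder or common disease alleles
are exempt — founder alleles (e.g. the STAC3 myopathy variant, the most
frequent cause of recessive myopathy in African-ancestry patients) can be
common enough to fail naive rarity filters. Variants with no frequency data
are retained. The source workflow states no numeric cutoffs; these defaults
are conventional Mendelian-filtering values and are config-overridable.

### Zygosity consistency

Per gene-disease inheritance mode (declared in panel metadata or config):
dominant accepts any carrier genotype; recessive accepts homozygous, calls
a single heterozygous hit `carrier_only`, and upgrades to
`provisional_compound_het` when a second qualifying heterozygous variant
exists in the same gene — provisional because singleton data cannot phase
the pair. X-linked recessive accepts hemizygous males and homozygous
females; heterozygous females are carriers. Genes with no declared mode are
evaluated under all applicable modes with the most permissive verdict
reported and flagged in the case notes.

## Evidence combination

The points scale (supporting/moderate/strong/very strong = 1/2/4/8;
benign-direction codes negative; BA1 = −8) with thresholds ≥10 / 6..9 /
0..5 / −6..−1 / ≤−7 was chosen over the 2015 rule-combination table because
curated sets in this workflow carry arbitrary strength modifiers
(`PM3_strong`, `PS3_moderate`, `PS2_very strong`) that the table cannot
express. On the seven curated sets of the replication cohort it reproduces
six printed labels exactly; the seventh (OCRL, 6 points) computes likely
pathogenic against a printed pathogenic. The engine deliberately does not
replicate that elevation: it emits its computed label plus a discrepancy
note whenever a supplied curator label disagrees. Token parsing accepts
case and underscore/space variation (`PS2_very strong` ≡ `PS2_VeryStrong`);
`PP5_supporting` is semantically identical to `PP5` (supporting is PP5's
default strength) but the explicit spelling is preserved for round-trip
formatting, matching the curators' convention.

Only annotation-derivable criteria are auto-assigned: PVS1 (null
consequence in a declared loss-of-function-mechanism gene),
PM2_supporting (every available MAF < 1e-4, or no frequency observed),
PP3/BP4 (majority of ≥2 available tools above/below their cut-offs:
CADD ≥ 20, REVEL ≥ 0.5, BayesDel ≥ 0.0692, MetaRNN ≥ 0.5 — each tool's
conventional operating point, all overridable), PP5_supporting (prior P/LP
ClinVar assertion with ≥1 review star, guarding against circularity from
unreviewed submissions) and BA1 (any MAF ≥ 0.05). Family, functional and
hotspot criteria (PS2–PS4, PM1, PM3, PM5, PP1, PP2, …) require human
judgement and enter only through curated evidence strings supplied in the
cascade config, keyed by (case, gene) — the software stand-in for the
study's manual-curation step.

## Synthetic cohorts

The generator emulates what the triage pipeline consumes, not raw
sequencing. Per case it draws a configurable number of *benign-consistent*
background variants (default 500, enough to exercise every filter while a
full 32-case run stays under ~2 s in memory): each is either common (MAF
from a scaled Beta component on roughly [0.02, 0.45], so the frequency gate
or BA1 removes it) or rare/novel with benign or absent ClinVar status and
in-silico scores below every cut-off. A small fraction of rare background
variants carries uncertain or conflicting ClinVar records so tier 2 has
realistic survivors. By construction, auto-assigned evidence on any
background variant sums to at most +1 point (PM2), so background can never
reach likely pathogenic — which makes the truth manifest of planted
causatives an exact oracle and the no-false-positive property testable by
brute force.

The canonical replication fixture plants the seven published diagnoses with
their reported gene, consequence, zygosity, ClinVar status and review
stars, curated evidence codes, read depth and demographic labels, into a
32-case manifest whose single-variable margins (site 17/15, sex 16/16,
referrer 23/9, ancestry 26/1/1/4, consanguinity 2/30, indications) equal
the published recruit table; joint structure among the 25 undiagnosed cases
is unconstrained by the source and filled deterministically. The fixture's
tier-1 and tier-3 panels are small synthetic stand-ins (the real 1,127- and
2,313-gene lists are supplementary material treated as user-supplied
files): the tier-1 panel contains exactly the five genes diagnosed there
and excludes SHOC2 and TRPV4, forcing tier attribution to match the
published 5/2/0 split. Planted gene coordinates are plausible GRCh37-like
anchors plus the cDNA offset; coordinate realism is a non-goal, as are read
simulation, error models and haplotype structure.

All randomness derives from one integer seed (per-case streams are spawned
from (seed, case index)); regeneration is byte-identical. Because
background is benign-consistent, the cohort-level outcomes (7 positives,
yield 21.9%, stratum yields) are invariant to the seed — a deliberate
property: the seed varies the nuisance background, not the stated world.

A green replication test therefore establishes that the cascade, combiner,
consistency rules and reporting reproduce the published accounting *given*
the published per-variant interpretations; it does not establish that the
pipeline would reach the same interpretations from raw reads, nor the
study's real-world 22% yield on undeposited patient exomes.

## Reporting

Yield and stratum percentages are rounded to one decimal, half-up, matching
the published table's printed values (7/32 → 21.9, 6/17 → 35.3, 3/9 →
33.3). The published table prints "−23.3" for the non-consanguineous
positive percentage; this is arithmetically 7/30 = 23.3 and the summary
computes 23.3 — the sign is treated as a typographical error and not
replicated. Case reports carry only pathogenic/likely-pathogenic findings
(gene, HGVS, zygosity, classification, evidence string in the curated
format, discovery tier); negative reports state that no reportable variant
was found across the three strategies.

## Numerical and degenerate-input choices

- Empty cohort: yield is undefined (error from `diagnostic_yield`; `None`
  from the result object, with a warning).
- Equal prioritization keys preserve input order (stable sort); two
  qualifying causatives in one tier resolve to the higher-ranked one.
- Frequency comparisons are inclusive (`maf <= cutoff` retained), so a
  variant exactly at a cutoff survives.
- Evidence sets reject duplicate criterion IDs; an empty set is 0 points
  (uncertain significance).
- Unknown consequence terms rank below synonymous ("other"); unknown
  contigs sort after MT.

## Known limitations

- Panels match by gene symbol only; no alias resolution. Annotation source
  and panel files must share a symbol vocabulary.
- Singleton design: no trio logic, no de novo inference, compound
  heterozygotes are reported unphased and provisional.
- No CNV/structural-variant support; multi-sample VCFs are rejected.
- The auto-assigner covers six criteria; everything else requires curated
  input, so fully automatic classification of novel variants is
  intentionally conservative (tends toward VUS).
- Tier-2 retention depends entirely on upstream ClinVar annotation quality
  and version.
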