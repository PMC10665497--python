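# exotriage

Tiered virtual-gene-panel triage of singleton clinical exomes, with
strength-modifier-aware ACMG/AMP classification and cohort-level
diagnostic-yield reporting.

## The problem

Clinical exome sequencing (CES) can end a diagnostic odyssey for critically
ill infants, but in resource-constrained settings the analysis must be
simple, fast and tolerant of the under-representation of African genomes in
reference databases. A pragmatic strategy used in South African neonatal
intensive-care cohorts is a *sequential cascade of virtual panels*: analyse
a singleton proband's annotated variants against

1. a curated panel of neonatal- and early-childhood-onset disease genes,
   extended with genes carrying known African founder and common variants
   (**tier 1**, "NICU/African");
2. if no causative variant is found, all variants with prior pathogenic,
   likely-pathogenic or uncertain ClinVar assertions, including conflicting
   interpretations (**tier 2**);
3. failing that, the DDG2P developmental-disorder gene panel (**tier 3**).

Within a tier, survivors are ranked for curation (prior P/LP ClinVar
assertions, consequence severity, allele rarity, in-silico support), and a
case is *positive* when a candidate classifies pathogenic or likely
pathogenic **and** its zygosity is consistent with the gene's inheritance
mode (hemizygous male for X-linked recessive, homozygous or provisional
compound-heterozygous for recessive, any carrier genotype for dominant).
The first such variant stops the cascade; later tiers are never evaluated.

This package implements that workflow as a tested, reusable library, for
clinical bioinformaticians and researchers who want to run, probe or extend
the strategy on their own annotated VCFs — plus a seeded synthetic-cohort
generator that replicates the 32-infant study cohort the workflow was
developed on, including its seven diagnoses (STAC3, MTM1, COL2A1, SHOC2,
OCRL, NPHS1, TRPV4).

## Classification model

Curators apply ACMG/AMP evidence criteria at modified strengths (e.g.
`PM3_strong`, `PS2_very strong`, `PVS1_strong`). The original 2015
rule-combination table cannot express such sets, so the engine combines
evidence on the Bayesian points scale: supporting/moderate/strong/very
strong = 1/2/4/8 points, negated for benign-direction codes (BA1 = −8), and

| total points | label |
|---|---|
| ≥ 10 | pathogenic |
| 6 – 9 | likely pathogenic |
| 0 – 5 | uncertain significance |
| −6 – −1 | likely benign |
| ≤ −7 | benign |

Six of the seven curated code sets of the replication cohort reproduce their
printed labels exactly; the seventh (`PVS1_strong, PM2_supporting,
PP5_supporting` = 6 points) computes likely pathogenic where the curators
printed pathogenic — the engine reports its own label and attaches a
discrepancy note rather than silently replicating the elevation.

## Worked example

```sh
python examples/cohort_yield_report.py
```

builds the 32-case replication cohort (500 benign-consistent background
variants per case, seven planted causatives), runs the cascade and prints:

```
cases analysed:      32
positive diagnoses:  7
diagnostic yield:    21.9%
discovery tiers:     {'panel': 5, 'clinvar': 2}

stratified yield:
                             stratum  n_recruited  percent_of_cohort  n_positive  percent_positive
                           site=NMCH           15               46.9           1               6.7
                          site=RMMCH           17               53.1           6              35.3
                          sex=female           16               50.0           3              18.8
                            sex=male           16               50.0           4              25.0
                 referrer=Geneticist            9               28.1           3              33.3
referrer=Neonatologist/Paediatrician           23               71.9           4              17.4
```

A yield of 21.9% means 7 of 32 infants received a pathogenic or
likely-pathogenic, inheritance-consistent molecular finding; five of the
seven were discovered on the NICU/African virtual panel and two via the
ClinVar filter. The other scripts under `examples/` demonstrate evidence
combination, single-case triage, filtering/prioritization and on-disk
fixture generation.

Typical library use on real data:

```python
from exotriage import load_panel, read_annotated_vcf, run_case, TriageConfig

nicu = load_panel("nicu_african_panel.tsv", "NICU/African")
ddg2p = load_panel("ddg2p.tsv", "DDG2P")
variants = read_annotated_vcf("proband.vep.vcf", case_id="P001")
result = run_case("P001", variants, "male", nicu, ddg2p, TriageConfig())
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the replication fixture from scratch (VCFs written to a
temporary directory and re-read through the normal I/O path), runs the full
cascade on all 32 cases and writes the recomputed cohort diagnostic yield
and the RMMCH- and geneticist-stratum yields as JSON. The planted outcomes
are deterministic by construction, so the values do not depend on the seed.

See `docs/methods.md` for the model assumptions, default thresholds, what
the synthetic generator does and does not emulate, and known limitations.
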