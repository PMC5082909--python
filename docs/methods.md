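# Methods

This note records the models, conventions and design decisions behind
`eacnv`, in the spirit of the methods documentation of mature
scientific packages: what is computed, under which assumptions, with
which defaults, and what the synthetic validation does and does not
demonstrate.

## Coordinates and interval arithmetic

All genomic coordinates are 1-based and inclusive at both ends, the
convention of SNP-array caller output and of the published candidate
tables this package reproduces. BED input (0-based, half-open) is
converted at the file boundary and nowhere else. Chromosome labels are
stored without a `chr` prefix.

Sizes in kb round half away from zero. Two in-text sizes in the source
cohort's narrative differ by 1 kb from its table (227 vs 228, 133 vs
134); the tables are treated as canonical, and the reconstruction test
requires exact agreement with them.

`coverage_fraction` measures the fraction of a query interval covered
by the *union* of features, never double-counting overlaps;
`reciprocal_overlap` is the minimum of the two directed coverage
fractions. Both are validated against per-base enumeration oracles in
the test suite, including a 10,000-configuration randomized sweep.

## Dual-caller harmonization

Confidence floors are the two callers' published defaults: 35
(partition-style) and 10 (penn-style), with a minimum of three
consecutive probes for any call. Fragmented same-state calls from one
caller re-merge when the inter-call gap is at most a fraction
(default 0.2, the referenced merge utility's documented default) of
the span the merge would produce, iterating to a fixed point; probe
counts add and the merged confidence is the pair minimum
(conservative).

Cross-caller concordance is not defined numerically in registry
reports; this package uses the field convention of ≥ 50 % reciprocal
overlap with matching CNV direction. The union of calls — not the
concordant intersection — feeds selection, with the concordance label
carried as metadata. When both callers report the same event in the
same sample, the post-selection deduplication step keeps one
representative, preferring the penn-style segmentation (matching the
convention of the reported tables) and recording both callers.

Runs of homozygosity are maximal stretches of AA/BB genotypes
(no-calls tolerated, any AB terminates), requiring ≥ 1 Mb span and
≥ 50 homozygous probes. The probe floor is an extension beyond the
1 Mb rule: it prevents spurious ROH across probe-sparse regions and is
configurable.

## Candidate selection

Autosomal candidates need ≥ 10 probes, ≥ 25 kb, and strictly less
than 35 % coverage by every same-type reference set. The 35 % rule is
interpreted as the fraction of the *case call* covered by the union of
same-type reference features (query-fraction, not reciprocal), the
laxer and more literal reading of "overlap with" a polymorphism
catalogue. `both`-typed reference entries match either CNV direction.

The DGV-style exclusion is deliberately different: entries are judged
*individually*, and a call is excluded only when at least 2 same-type
entries each cover at least 50 % of it. "Several catalogued variants
that each look like this call" is evidence of a population
polymorphism; many small fragments tiling across it are not. Both
thresholds are configurable.

Sex-chromosome calls face the same size floor and reference rules
after removal of copy-number-2 calls inside PAR/XTR, which are normal
diploid state in both sexes. Expected ploidy is sex-aware (female X 2,
male X/Y 1, PAR/XTR 2 for everyone), and CNV direction is judged
against it.

The audit trail records, for every rejected call, the *first* rule
that removed it, in the order size → probes → common-reference →
DGV. Size is checked before probes so that a call failing both floors
is attributed to the more fundamental deficiency.

Manual review of log-R-ratio/B-allele-frequency plots is replaced by a
rule: a candidate fails review when the mean LRR across its probes is
below 0.1 in magnitude or has the wrong sign for its copy-number
direction. This is a stand-in for human judgment, not a reproduction
of it; candidates without probe data keep their flag.

Recurrence groups same-type candidates of *different* cases at ≥ 50 %
reciprocal overlap, with transitive closure; each connected group
receives one CNV identifier (ordinals in genomic order) and its
distinct-case count.

## Variant triage

Allelic balance alt/(ref+alt) partitions into `likely_artifact`
(< 0.25), `expected_het` (0.40–0.85) and `review` (everything else,
including near-homozygous values). The bands are the empirically
motivated ones from targeted-capture practice: at depth ≥ 30 a true
heterozygote falls inside 0.40–0.85 with probability ≈ 0.96–0.99,
while reference-biased artifacts concentrate far below 0.25.

The rarity ceiling defaults to a population allele frequency of 0.005
— above the largest frequency among the validated variants this
package's reference tables carry (2.29 × 10⁻³) and below common
polymorphism territory; absent frequencies pass. Candidate-gene
variants additionally require a predicted-impact annotation
(loss-of-function / high-impact / pathogenic-by-multiple-predictors),
which is consumed as an input flag — pathogenicity prediction itself
is out of scope. The case-level summary counts distinct samples
carrying reported variants in the cardiomyopathy panel
{MYH7, MYH6, TTN, TCAP, JUP}.

## Enrichment

The test statistic is the one-sided hypergeometric tail on the 2×2
overlap table (the Fisher exact one-sided p), computed with
`scipy.stats.hypergeom` and cross-validated against exhaustive tail
enumeration for all universes ≤ 25 genes. External enrichment services
layer rank-based corrections on top of this statistic; the
hypergeometric core is the reproducible component and is what this
package implements. Multiple testing uses Benjamini–Hochberg within
each query list. The background universe defaults to the union of all
library members and can be supplied explicitly.

Exclusion rules drop sets with adjusted P ≥ 0.05, sets whose overlap
is only the three known disease genes, sets whose overlap genes all
derive from a single CNV (known genes carry a sentinel pseudo-id and
do not count as a CNV by default), and deletion-/duplication-list
results whose set also survives on the all-CNVs list. The rules are
order-independent.

Enrichment-map edges use the overlap coefficient with an *inclusive*
0.5 cutoff; clusters are connected components labelled by their
alphabetically smallest member, making the map deterministic under
input reordering.

## Cohort statistics

Birth prevalence is reported as "1 in N" with N rounded to the nearest
hundred. Chi-square tests are classical Pearson on the categories ×
(population, cases) table without continuity correction, df =
categories − 1; cases are compared against all births including
themselves, exactly as registry tables present it. Percentages round
half away from zero through an intermediate two-decimal stage — the
convention reverse-engineered from the reference table, where e.g.
48.7485 % prints as 48.8 (48.75 → 48.8) rather than 48.7.

## Synthetic cohorts

The generator emulates the study's inputs at desk scale: two autosomes
(60 and 45 Mb), an X and Y with declared PAR (first 300 kb) and XTR
(5.0–5.5 Mb) spans, probes every 2 kb (a reduced version of the
~1.2 kb density of the emulated array) with a 6-fold sparser window on
chromosome 2 hosting the low-probe event class. Default 20 cases.

Planted events per cohort: 8 rare candidates (40–150 kb; the first is
duplicated into a second case as a recurrent pair), 5 common
polymorphisms (placed identically into the reference sets), 3
DGV-like events (two same-type catalogue entries each covering ~80 %),
2 artifacts (intensity-unsupported), 2 sub-size events (8–15 kb) and 2
low-probe events (45–60 kb in the sparse window), plus one female X
duplication and one diploid PAR record. Each planted event carries
exactly one expected fate in the truth table.

Caller noise: each caller misses an event with probability 0.05,
draws a below-threshold confidence with probability 0.10, jitters
boundaries with sd 2 kb, splits a call with probability 0.02 (the
merge step re-joins these), and emits ~3 false-positive calls per
sample, all below the 25 kb floor. Per-probe log R ratios draw from
N(−0.45, 0.133) in losses, N(+0.3, 0.133) in gains and N(0, 0.133)
elsewhere — standard array practice for the state means, with the
deviation reported for the emulated array data. B-allele frequencies
follow copy number (homozygous-only in losses, 0.33/0.67 bands in
gains). Sequence variants draw alternate reads from Binomial(depth,
0.5) for true heterozygotes and Binomial(depth, 0.1) for artifacts,
depth ~ Poisson(60) floored at 30.

With a fixed seed the bundle is byte-identical across runs; all
randomness flows from one `numpy` Generator and every file is written
in sorted order.

**What passing the synthetic checks shows** — that the selection rules
implement their definitions: events violating a floor or matching a
reference set are removed for the right reason, rare planted events
survive at the rate implied by the caller-noise model (the ~1–2 % loss
is exactly the both-callers-missed probability, not a filtering
error), recurrent pairs group, and artifacts fail review. **What it
does not show** — performance on real arrays: the generator has no
genomic wave, no LD structure, no population stratification, no
probe-specific error, and its callers are emission models rather than
HMM segmenters. Detection sensitivity of the upstream callers is
explicitly out of scope.

## Reference tables

The published cohort summary tables (candidate CNVs, validated
variants, demographics) ship as package data. They serve two roles:
regression fixtures — sizes, counts and percentages must reproduce
from raw coordinates and counts — and inputs to the cohort-statistics
stage. The exclusion-cascade narrative reports both the pre-validation
(26 cases / 55 %) and post-validation (24 cases / 51 %) carrier
counts; the shipped table is the post-validation one, and the package
reports whichever its caller computes rather than choosing.

## Numerical and degenerate-input conventions

Zero-depth variants, empty gene-set backgrounds, empty percentage
columns, zero chi-square marginals, negative merge gap fractions,
unknown sample sexes and unsorted probe streams all raise
`ValueError`/`KeyError` with a message naming the offending input.
Boundary semantics are: confidence floors inclusive (≥), probe/size
floors inclusive, reference-overlap ceiling strict (< 35 %),
allelic-balance artifact band right-open (< 0.25), heterozygote band
closed ([0.40, 0.85]), enrichment-map cutoff inclusive (≥ 0.5).
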