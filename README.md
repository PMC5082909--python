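# eacnv

**CNV discovery and prioritization for isolated Ebstein anomaly cohorts.**

Ebstein anomaly (EA) is a rare congenital heart defect in which the
tricuspid valve is malformed and displaced into the right ventricle.
Its genetic basis is heterogeneous: coding mutations in *MYH7*,
*NKX2-5* and *GATA4* explain only a minority of cases, and rare copy
number variants (CNVs) are a plausible additional source of risk.
`eacnv` implements, as a reusable and tested Python library, the full
analytical arm of a registry-based genome-wide CNV study of isolated
EA: from raw dual-caller SNP-array CNV output to a prioritized
candidate table, rare sequence-variant triage, gene-set enrichment
with an enrichment map, and cohort prevalence statistics. A seeded
synthetic-cohort generator with planted ground truth makes every stage
testable end to end without any external data.

## The method

CNVs are called twice per sample (a PennCNV-style caller and a
GenomeStudio/cnvPartition-style caller). The pipeline then applies, in
order:

1. **Harmonization** — confidence floors (≥ 35 partition-style, ≥ 10
   penn-style, ≥ 3 consecutive probes for either), re-merging of
   fragmented calls (gap ≤ 20 % of the merged span, iterated to a
   fixed point), and cross-caller concordance labels at ≥ 50 %
   reciprocal overlap. The union of calls is carried forward.
2. **Candidate selection** — autosomal calls survive with ≥ 10 probes,
   ≥ 25 kb, and **< 35 %** coverage of the call by the union of each
   same-type reference set (HapMap3 common copy-number polymorphisms,
   CHOP CNV blocks, project controls, an unrelated birth-defect case
   database); calls covered ≥ 50 % by ≥ 2 same-type entries of a
   DGV-like catalogue are excluded. Sex-chromosome calls face the same
   rules after removing copy-number-2 spans in PAR/XTR (diploid in
   both sexes). A log-R-ratio consistency check stands in for manual
   intensity-plot review. Same-type candidates in different cases with
   ≥ 50 % reciprocal overlap are grouped as one recurrent CNV.
3. **Annotation** — any-overlap transcript intersection, candidate-gene
   list flags, and overlap/distance against known EA genes.
4. **Variant triage** — allelic balance ``alt/(ref+alt)``: < 0.25 is a
   likely artifact, 0.40–0.85 an expected heterozygote; variants must
   be rare (population allele frequency < 0.005 or absent), and
   candidate-gene variants additionally need a predicted-impact flag.
5. **Enrichment** — three query lists (all candidate CNV genes,
   deletion genes, duplication genes, each plus the three known EA
   genes) tested per gene set with the one-sided hypergeometric
   (Fisher) test, Benjamini–Hochberg adjusted; sets are pruned
   (adjusted *P* ≥ 0.05, known-genes-only, single-CNV, redundant
   deletion/duplication results) and linked into an enrichment map
   whenever the member overlap coefficient |A∩B|/min(|A|,|B|) ≥ 0.5.
6. **Cohort statistics** — 1-in-*N* birth prevalence (nearest 100),
   audited exclusion cascade, Pearson chi-square demographics.

## Worked example

Simulate a 20-case cohort and run every stage:

```sh
eacnv run-all --seed 7 --out runs/demo
```

prints the run summary (abridged):

```json
{
  "candidates": 11,
  "candidates_pass_review": 9,
  "cases_with_candidate": 9,
  "concordant_both": 32,
  "raw_calls": {"partitionstyle": 76, "pennstyle": 74},
  "recurrent_groups": 1,
  "selection_reasons": {
    "filtered_common": 7, "filtered_dgv": 6, "filtered_par_xtr": 1,
    "filtered_probes": 3, "filtered_size": 88, "retained": 19
  },
  "gene_sets_surviving": 1,
  "variants_reported": 30
}
```

Of 150 raw calls, most are sub-threshold noise (88 below 25 kb,
3 under 10 probes); 7 calls match planted common polymorphisms and 6
match the DGV-like catalogue; 19 retained calls collapse to 11
candidate events (one recurrent pair shared by two cases), of which 9
pass the intensity review — exactly the planted rare events. The
planted enriched pathway is the single surviving gene set. The first
rows of `runs/demo/candidates.tsv`:

```text
CNV #  Study ID  Type  CN  ...  Chrom  Start    End      ~Size (Kb)  Recurrent
1      S014      Dupl  3   ...  1      999935   1145707  146         True
1      S019      Dupl  3   ...  1      999936   1145617  146         True
```

Each pipeline stage is also exposed separately (`eacnv simulate`,
`harmonize`, `select`, `annotate`, `triage`, `enrich`, `stats`) and as
plain library functions.

## Layout

```
src/eacnv/
  intervals.py    1-based closed-coordinate interval arithmetic
  models.py       domain records (calls, candidates, variants, references)
  io_formats.py   caller dialects, BED/GTF, GMT, VCF/TSV, report tables
  harmonize.py    thresholds, merging, concordance, ROH detection
  selection.py    candidate selection, DGV rule, recurrence, LRR review
  annotate.py     transcript and gene-list annotation
  variants.py     allelic-balance triage
  enrichment.py   hypergeometric enrichment + enrichment map
  cohort.py       prevalence, exclusion cascade, chi-square
  simulate.py     synthetic cohorts with planted truth
  pipeline.py     stage orchestration and truth evaluation
  cli.py          command-line interface
  datasets/       published cohort reference tables (TSV)
```

See `docs/methods.md` for the modelling choices, parameter defaults
and known limitations.
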