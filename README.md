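# nbexome

Downstream analysis of tumor/normal exome cohorts in clinically aggressive
neuroblastoma — everything that happens *after* variant calling and
annotation. The package takes annotated somatic and germline variant tables
(with per-variant read support and externally computed CHASM/VEST
pathogenicity p-values) and produces the study-level results a cancer
genomics group reports:

* **Somatic filtering** — a fixed cascade (depth → alt reads → tumor VAF →
  normal VAF → dbSNP → functional class) reducing raw calls to a
  high-confidence non-silent set, with a per-rule rejection audit, plus the
  HR-Event3 clinical subgroup classifier (high-risk patients with an adverse
  event within 36 months of diagnosis).
* **Mutation spectra and signatures** — SNVs binned into the 96
  pyrimidine-strand trinucleotide classes `X[R>A]Y`; substitution-class
  fractions; cosine comparison between spectra; and signature exposures by
  non-negative least squares: `min_w ||f − Pw||₂, w ≥ 0`, weights
  renormalized to sum to 1.
* **Driver prioritization** — per-gene combination of mutation-level CHASM
  and VEST p-values (Fisher's method, `χ²_{2k}` on `−2Σln p`),
  Benjamini–Hochberg FDR across genes, and the dual significance gate
  **CHASM FDR < 0.25 AND VEST FDR < 0.1**; carrier frequencies reported to
  one decimal percent of the cohort.
* **Pathway enrichment** — pre-ranked GSEA over genes ranked by
  `−log10(CHASM gene p)`: weighted Kolmogorov–Smirnov running statistic,
  gene-label permutation null, NES, and the pooled-NES FDR, plus per-pathway
  carrier and mutual-exclusivity summaries.
* **Germline rare-variant burden** — candidate filtering (predisposition
  genes, non-dbSNP, VEST p < 0.10), per-cohort two-sided Fisher's exact
  tests (minimum-likelihood rule, evaluated in log space), a combined p
  from pooling all control cohorts into one 2×2 table, and fold enrichment.
  The published per-gene carrier counts ship as a packaged fixture.
* **Synthetic cohorts** — a seeded generator for every input (variant
  tables with signature-mixture contexts, driver/passenger score
  distributions, case–control carrier tables), so the full pipeline is
  testable end to end without any data download.

## Worked example

The germline burden analysis from the packaged carrier counts:

```python
from nbexome import burden_report, load_table1_counts

for row in burden_report(load_table1_counts())[:4]:
    print(row.gene_symbol, {c: round(p, 3) for c, p in row.cohort_p.items()},
          round(row.combined_p, 4))
```

prints

```
BARD1 {'1000g_ita': 0.057, '1000g_eur': 0.002, 'house_ita': 0.058} 0.0004
AXIN2 {'1000g_ita': 0.011, '1000g_eur': 0.004, 'house_ita': 0.041} 0.0019
MC1R  {'1000g_ita': 0.297, '1000g_eur': 0.001, 'house_ita': 0.116} 0.0056
CHEK2 {'1000g_ita': 0.034, '1000g_eur': 0.023, 'house_ita': 0.034} 0.0078
```

Each line is one predisposition gene: the two-sided Fisher p-value of its
case carrier count against each control cohort, then the combined p against
all 609 pooled controls. BARD1 (4 carriers among 104 patients, none among
controls) leads the table; AXIN2 and CHEK2 follow among the reported genes.

The `examples/` directory holds one short narrative script per capability
(simulation + filtering, spectra + signatures, drivers + pathways, burden
table); each prints the numbers it computes and what they mean. A thin CLI
(`nbexome simulate | somatic-filter | spectrum | signatures | drivers |
pathways | germline-burden | run-all`) wraps the same functions for shell
use; `run-all` chains every stage and writes a manifest with input/output
digests so a fixed configuration and seed reproduce identical artifacts.

## Layout

```
src/nbexome/       library (io, simulate, filtering, spectrum, drivers,
                   gsea, burden, pipeline, cli)
src/nbexome/data/  packaged carrier-count fixture
examples/          narrative scripts, one per capability
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance script
docs/methods.md    methods note: models, defaults, numerical choices
```
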