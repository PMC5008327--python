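# Methods

This note documents the models, defaults and numerical choices behind
`nbexome`, and what the synthetic cohorts do and do not establish about
real data.

## Somatic filter cascade

Raw tumor/normal calls are filtered by six rules applied in a fixed order:
tumor and normal sequencing depth, tumor alt-read support, tumor variant
allele fraction (VAF), normal VAF, dbSNP membership, functional class.
The order matters only for the audit: each rejected call is charged to the
*first* rule it fails, so rejection counts are reproducible and sum to the
number of rejected calls. Filtering is idempotent, and relaxing any single
threshold can only grow the retained set (property-tested).

Defaults — `min_tumor_depth 14`, `min_normal_depth 8`,
`min_tumor_alt_reads 4`, `min_tumor_vaf 0.10`, `max_normal_vaf 0.05`,
`exclude_dbsnp true` — reflect common tumor/normal practice of the
VarScan2 era; the thresholds used in the original study were not published,
so every one is exposed in `FilterConfig`. "Non-silent" means
{missense, nonsense, splice_site, frameshift_indel, inframe_indel}; silent
and noncoding calls are excluded. The per-sample summary reports the
*lower* median (the smaller central order statistic for an even number of
samples), so the reported value is always a realized per-sample count.

The HR-Event3 subgroup is high-risk **and** an adverse event (progression,
relapse, death) **and** months-to-event ≤ 36, boundary inclusive.

## 96-context spectra and signature exposures

Single-base substitutions with their 5′ and 3′ neighbors define 192
strandwise mutation types; reverse-complementing purine-reference
mutations onto the pyrimidine strand collapses these onto 96 classes
(6 substitution classes × 16 flank combinations), each hit exactly twice
in the exhaustive enumeration. Bin order is the COSMIC lexicographic
convention: substitution class major (C>A, C>G, C>T, T>A, T>C, T>G), then
5′ base, then 3′ base, with labels like `T[C>A]T`.

Signature exposures solve non-negative least squares on the
frequency-normalized spectrum, `min_w ||f − Pw||₂, w ≥ 0` (via
`scipy.optimize.nnls`), and report weights renormalized to sum to one;
`residual_norm` is the pre-renormalization objective. NNLS was chosen
because it is the standard attribution model for fixed reference profiles
and is verifiable against a brute-force simplex grid search — agreement is
within the grid step on mixtures whose residual is small, which is the
regime exposure fitting is meant for. Cross-dataset spectrum comparison
uses cosine similarity on frequency vectors (a quantitative stand-in; the
underlying comparison in the literature is qualitative). De novo signature
extraction (NMF) is out of scope.

## Driver prioritization

Per-mutation CHASM-style and VEST-style p-values are consumed as input
(the classifiers themselves are upstream tools). Gene-level combination
defaults to Fisher's method — `−2Σ ln p ~ χ²` with 2k degrees of freedom —
the convention of the CRAVAT family from which those scores come;
`min_p_bonferroni` is available for sensitivity analysis. Zero p-values
are clamped to 1e-300 with a warning. FDR across genes is
Benjamini–Hochberg step-up, `q_(i) = min_{j≥i} m·p_(j)/j`, tested exactly
against a quadratic-time oracle and statsmodels. A gene is significant
only if **both** gates pass: CHASM FDR < 0.25 and VEST FDR < 0.1.

Carrier frequency is distinct mutated samples over the cohort size,
reported to one decimal percent (4/99 → 4.0%, 8/99 → 8.1%). Carrier
counting is per sample, so duplicated mutation rows within a sample do not
inflate it.

## Pre-ranked GSEA

Genes are ranked by `−log10` of the gene-level CHASM p (descending, ties
broken lexicographically so the ranking is deterministic). For a set with
`N_h` members among `N` ranked genes, the running statistic increments at
hits by `|s|^w / Σ_hits |s|^w` and decrements at misses by `1/(N − N_h)`;
the enrichment score is the extremum by absolute value. The weight
exponent defaults to 1 (the classic weighted statistic). If every member
score is zero the statistic falls back to unweighted increments rather
than dividing by zero.

The null permutes gene labels (member identities re-drawn uniformly;
scores stay fixed) — sample permutation has no meaning for a mutation
ranking. The nominal p uses the add-one estimator against the same-sign
permutation pool, `p = (1 + #{perm ES at least as extreme}) /
(n_same_sign + 1)`, which is never zero and is uniform under the null
(sign-conditioning makes each one-sided comparison exchangeable). NES
divides ES by the mean same-sign permutation ES magnitude; FDR follows the
canonical pooled procedure: the fraction of pooled same-sign permutation
NES at least as extreme, divided by the fraction of observed NES at least
as extreme, capped at 1. Permutation ES values are computed vectorized
from sorted hit positions (the running sum is piecewise linear between
hits, so its extremum lies just after or just before a hit); the batched
computation is tested to agree exactly with the sequential statistic.

## Germline burden testing

Candidate germline variants are kept iff the gene is in the curated
predisposition list, the variant is not a common polymorphism (dbSNP flag)
and its VEST p is **strictly** below 0.10. Per gene, the case carrier 2×2
table is tested against each control cohort with a two-sided Fisher's
exact test under the minimum-likelihood rule: the p-value sums
hypergeometric point probabilities over the fixed-margin support that do
not exceed the observed table's probability (relative tolerance 1e-7),
evaluated in log space with `lgamma` and log-sum-exp. This rule — not the
one-sided tail — is the one consistent with the published table (e.g. the
MC1R/in-house cell is 0.116 two-sided vs ≈0.078 one-sided).

The combined p pools all control cohorts by summing carrier/non-carrier
counts into one 2×2 table and testing once. Pooling, rather than
combining the three per-cohort p-values, reproduces the published combined
column exactly (Fisher's method on the p-values does not). Per-gene case
totals come from the input — one gene was assayed in 104 patients, the
rest in 52 — so inconsistent cohort sizes across genes produce a warning,
not an error.

Fold enrichment is the case carrier frequency over the pooled-control
carrier frequency, with a pseudocount (default 1) added to the control
carriers only when none were observed. The published fold column cannot be
reproduced by any single pooled-ratio/pseudocount formula we tried, so it
is treated as data where needed and the formula here is exposed with its
pseudocount parameter rather than fit to the printed values.

Note on ordering: by combined p the packaged table ranks BARD1, AXIN2,
MC1R, CHEK2 — MC1R's pooled p (0.0056) genuinely sits between AXIN2 and
CHEK2, as in the published table; the three *reported* burden genes are
BARD1, AXIN2 and CHEK2.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with defaults matching the study scale: 17 tumor/normal pairs, per-sample
mutation counts Poisson with mean 17, tumor VAF ~ Beta(8, 12) (clonal
mutations in tumors of ≳75% purity), sequencing depth ~ Poisson(110),
normal alt counts binomial at a 1e-3 error rate. Trinucleotide classes are
drawn from a mixture over signature profiles; two synthetic,
well-separated built-in profiles (a C>T deamination-like process peaking
at NpCpG and a C>A process peaking at TpCpT) stand in for published
references and are labelled synthetic. Passenger mutations scatter over a
2,000-gene pool, giving the long tail of genes hit once or twice that real
cohorts show; planted driver genes add Bernoulli per-sample mutations with
Beta-distributed (default Beta(1, 50)) pathogenicity p-values, against
Uniform(0, 1) passengers. Carrier tables are Binomial draws from per-gene,
per-cohort frequencies.

All generators are pure functions of (spec, seed): each sample draws from
a sub-stream derived by stably hashing its sample id with the global seed,
so output is independent of iteration order. `planted_cohort` bundles a
99-sample configuration with one strong driver, one six-gene pathway and
one burden gene for end-to-end validation.

What passing tests show — and don't: recovery of planted signatures,
drivers, pathways and burden genes demonstrates that the statistics are
implemented correctly and calibrated under their own assumptions
(independent mutations, clean clonal VAFs, honest uniform passenger
scores). Real cohorts violate these in ways the generator does not model:
subclonality and purity variation, copy number, correlated scores within
genes, panel-versus-exome depth heterogeneity, population structure in
control cohorts. Results on real data therefore inherit the caveats of
the upstream callers and classifiers, not just of these statistics.

## Problem sizes and numerical conventions

Test and validation runs use sizes chosen to make sampling error
negligible relative to each tolerance: 50,000 multinomial draws for
exposure recovery (±0.02), 500 random sets × 200 permutations for null-p
uniformity, 1,000 permutations for planted-set detection, 1,000 random
2×2 tables with margins up to ~1,000 for Fisher oracle equivalence, and a
99-sample simulated cohort for end-to-end recovery. Exact-test p-values
are compared to enumeration oracles at 1e-9; BH-FDR is compared exactly.
Degenerate inputs are errors, not silent results: empty spectra, empty
p-value lists, all-zero 2×2 tables, gene sets with no overlap with the
ranked list, SNVs lacking contexts. Ties in the GSEA extremum resolve to
the positive side; ranking ties resolve lexicographically; the per-sample
median is the lower median.
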