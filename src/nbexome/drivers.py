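"""Gene-level driver prioritization from per-mutation pathogenicity p-values.

Each non-silent mutation carries two externally computed p-values: a
CHASM-style p (probability the mutation is a passenger rather than a cancer
driver) and a VEST-style p (probability it is functionally neutral).  Per
gene, mutation p-values are combined (Fisher's method by default), genes are
corrected across the cohort by Benjamini-Hochberg, and a gene is called
significant when it passes BOTH gates: CHASM FDR < 0.25 and VEST FDR < 0.1.

Carrier frequency is the fraction of cohort samples with at least one
non-silent mutation in the gene, conventionally reported to one decimal
percent (4/99 -> 4.0%).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import VariantCall

logger = logging.getLogger(__name__)

CHASM_FDR_GATE = 0.25
VEST_FDR_GATE = 0.10

#: Columns identifying one mutation in a score table.
SCORE_KEY_COLUMNS = ("sample_id", "chrom", "pos", "ref_allele", "alt_allele")


@dataclass
class GeneDriverSummary:
    gene_symbol: str
    n_nonsilent_mutations: int
    n_carrier_samples: int
    carrier_frequency: float
    chasm_gene_p: float
    vest_gene_p: float
    chasm_fdr: float = float("nan")
    vest_fdr: float = float("nan")
    significant: bool = False

    @property
    def carrier_percent(self) -> float:
        """Carrier frequency as a percentage to one decimal place."""
        return round(100.0 * self.carrier_frequency, 1)


def gene_level_p(mutation_ps: Sequence[float], method: str = "fisher_combination") -> float:
    """Combine per-mutation p-values into one gene-level p.

    ``fisher_combination``: p from the chi-square distribution with 2k
    degrees of freedom evaluated at -2*sum(ln p).  ``min_p_bonferroni``:
    min(1, k * min(p)).  Zeros are clamped to 1e-300 with a warning.
    """
    if len(mutation_ps) == 0:
        raise ValueError("cannot combine an empty p-value list")
    ps = []
    for p in mutation_ps:
        if not (0 <= p <= 1):
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p == 0:
            logger.warning("p-value of 0 clamped to 1e-300")
            p = 1e-300
        ps.append(p)
    if method == "fisher_combination":
        statistic = -2.0 * sum(math.log(p) for p in ps)
        return float(stats.chi2.sf(statistic, df=2 * len(ps)))
    if method == "min_p_bonferroni":
        return min(1.0, len(ps) * min(ps))
    raise ValueError(f"unknown combination method {method!r}")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min over j >= i of m * p_(j) / j on the sorted p-values, mapped
    back to the original order; q is monotone in p and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def summarize_genes(
    variants: Iterable[VariantCall],
    scores: pd.DataFrame,
    n_samples: int,
    *,
    method: str = "fisher_combination",
    chasm_fdr_gate: float = CHASM_FDR_GATE,
    vest_fdr_gate: float = VEST_FDR_GATE,
) -> List[GeneDriverSummary]:
    """Aggregate mutations and pathogenicity scores to gene level.

    Parameters
    ----------
    variants
        Cohort variant calls; only non-silent ones contribute.
    scores
        Table with the key columns ``sample_id, chrom, pos, ref_allele,
        alt_allele`` plus ``chasm_p`` and ``vest_p``.  Every non-silent SNV
        must be scored; unscored indels still count toward carriers.
    n_samples
        Cohort size used as the carrier-frequency denominator; must be at
        least the number of distinct samples observed.
    """
    variants = [v for v in variants if v.is_non_silent]
    observed_samples = {v.sample_id for v in variants}
    if n_samples < len(observed_samples):
        raise ValueError(
            f"n_samples={n_samples} smaller than the {len(observed_samples)} samples observed"
        )
    score_map: Dict[tuple, Tuple[float, float]] = {}
    for row in scores.itertuples(index=False):
        key = tuple(getattr(row, c) for c in SCORE_KEY_COLUMNS)
        score_map[key] = (float(row.chasm_p), float(row.vest_p))

    by_gene: Dict[str, List[VariantCall]] = {}
    for v in variants:
        by_gene.setdefault(v.gene_symbol, []).append(v)

    missing = [v.key for v in variants if v.variant_class == "SNV" and v.key not in score_map]
    if missing:
        raise ValueError(f"{len(missing)} non-silent SNVs lack scores: {missing[:10]}")

    summaries: List[GeneDriverSummary] = []
    for gene in sorted(by_gene):
        muts = by_gene[gene]
        chasm_ps = [score_map[v.key][0] for v in muts if v.key in score_map]
        vest_ps = [score_map[v.key][1] for v in muts if v.key in score_map]
        if not chasm_ps:
            logger.warning("gene %s has no scored mutations; excluded", gene)
            continue
        carriers = {v.sample_id for v in muts}
        summaries.append(
            GeneDriverSummary(
                gene_symbol=gene,
                n_nonsilent_mutations=len(muts),
                n_carrier_samples=len(carriers),
                carrier_frequency=len(carriers) / n_samples,
                chasm_gene_p=gene_level_p(chasm_ps, method),
                vest_gene_p=gene_level_p(vest_ps, method),
            )
        )
    if not summaries:
        return summaries
    chasm_q = bh_fdr([s.chasm_gene_p for s in summaries])
    vest_q = bh_fdr([s.vest_gene_p for s in summaries])
    for s, cq, vq in zip(summaries, chasm_q, vest_q):
        s.chasm_fdr = float(cq)
        s.vest_fdr = float(vq)
        s.significant = bool(cq < chasm_fdr_gate and vq < vest_fdr_gate)
    return summaries


def summaries_to_frame(summaries: Sequence[GeneDriverSummary]) -> pd.DataFrame:
    """Tabulate summaries, one row per gene, for reporting."""
    return pd.DataFrame(
        {
            "gene_symbol": [s.gene_symbol for s in summaries],
            "n_nonsilent_mutations": [s.n_nonsilent_mutations for s in summaries],
            "n_carrier_samples": [s.n_carrier_samples for s in summaries],
            "carrier_percent": [s.carrier_percent for s in summaries],
            "chasm_gene_p": [s.chasm_gene_p for s in summaries],
            "vest_gene_p": [s.vest_gene_p for s in summaries],
            "chasm_fdr": [s.chasm_fdr for s in summaries],
            "vest_fdr": [s.vest_fdr for s in summaries],
            "significant": [s.significant for s in summaries],
        }
    )
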