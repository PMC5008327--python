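"""Pre-ranked gene-set enrichment over pathogenicity-ranked mutated genes.

Mutated genes are ranked by -log10 of their gene-level CHASM p-value and a
weighted Kolmogorov-Smirnov running statistic asks whether a pathway's genes
concentrate at the top of that ranking.  Walking down the list, hitting a
set member increments the running sum by its weighted score share
(|score|^w / sum over members of |score|^w); missing decrements by
1/(N - N_hits).  The enrichment score (ES) is the extremum of the running
sum by absolute value.

Significance comes from gene-label permutations: member labels are
re-assigned uniformly at random while the ranked scores stay fixed.  The
nominal p compares the observed ES with same-sign permutation ES values
using an add-one estimator, the normalized ES (NES) divides by the mean
same-sign permutation ES magnitude, and the FDR follows the canonical
pooled-NES procedure (all sets' permutation NES values pooled, same sign).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set, Tuple

import numpy as np

from .drivers import GeneDriverSummary
from .types import GeneSet, VariantCall


@dataclass
class RankedGeneList:
    """Genes in descending score order; ties broken lexicographically."""

    genes: list
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != self.scores.size:
            raise ValueError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique")
        for i in range(len(self.genes) - 1):
            a, b = self.scores[i], self.scores[i + 1]
            if a < b or (a == b and self.genes[i] > self.genes[i + 1]):
                raise ValueError("ranking not in (score desc, gene asc) order")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    fdr: float
    leading_edge: Set[str]


def rank_genes(summaries: Sequence[GeneDriverSummary]) -> RankedGeneList:
    """Rank genes by pathogenicity: score = -log10(CHASM gene p), descending,
    ties broken by gene symbol."""
    if not summaries:
        raise ValueError("no gene summaries to rank")
    pairs = sorted(
        ((s.gene_symbol, -math.log10(max(s.chasm_gene_p, 1e-300))) for s in summaries),
        key=lambda it: (-it[1], it[0]),
    )
    return RankedGeneList(genes=[g for g, _ in pairs], scores=np.array([x for _, x in pairs]))


def enrichment_score(
    ranked: RankedGeneList, gene_set: GeneSet, weight_exponent: float = 1.0
) -> Tuple[float, np.ndarray, Set[str]]:
    """Weighted KS enrichment score of one gene set.

    Returns ``(es, running_sum, leading_edge)`` where ``running_sum`` has one
    value per ranked gene (the statistic after processing that gene) and the
    leading edge contains the member genes at or before the extremum for a
    positive ES (after it for a negative ES).
    """
    hit_mask = np.array([g in gene_set.genes for g in ranked.genes])
    n = len(ranked)
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no overlap with the ranked list")
    if len(gene_set) > n:
        raise ValueError(f"gene set {gene_set.name!r} is larger than the ranked list")
    weights = np.abs(ranked.scores[hit_mask]) ** weight_exponent
    total = weights.sum()
    if total == 0:  # all member scores zero: fall back to the unweighted statistic
        weights = np.ones(n_hits)
        total = float(n_hits)
    steps = np.zeros(n)
    steps[hit_mask] = weights / total
    if n > n_hits:
        steps[~hit_mask] = -1.0 / (n - n_hits)
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    es = float(running[idx])
    if es >= 0:
        leading = {g for g, hit in zip(ranked.genes[: idx + 1], hit_mask[: idx + 1]) if hit}
    else:
        leading = {g for g, hit in zip(ranked.genes[idx:], hit_mask[idx:]) if hit}
    return es, running, leading


def _permutation_es(
    abs_scores_w: np.ndarray, n_hits: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES values for ``n_perm`` random label assignments of ``n_hits`` members.

    The running sum is piecewise linear between hits, so its extremum lies
    either just after a hit (candidate maximum) or just before one (candidate
    minimum); both are computed from the sorted hit positions alone.
    """
    n = abs_scores_w.size
    positions = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_hits]
    positions.sort(axis=1)
    w = abs_scores_w[positions]
    wsum = w.sum(axis=1, keepdims=True)
    zero = wsum[:, 0] == 0
    if np.any(zero):  # all-zero member scores: unweighted fallback
        w[zero] = 1.0
        wsum = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) / wsum
    ranks = np.arange(1, n_hits + 1)
    miss_dec = 1.0 / (n - n_hits) if n > n_hits else 0.0
    after = cum - (positions + 1 - ranks) * miss_dec
    before = np.concatenate([np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) - (
        positions + 1 - ranks
    ) * miss_dec
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


def gsea_preranked(
    ranked: RankedGeneList,
    sets: Iterable[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> List[EnrichmentResult]:
    """Run pre-ranked GSEA over a collection of gene sets.

    Nominal p uses the add-one estimator against same-sign permutation ES
    values; NES divides ES by the mean same-sign permutation ES magnitude;
    FDR pools permutation NES across sets as in the canonical procedure.
    Fully reproducible for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    sets = list(sets)
    rng = np.random.default_rng(seed)
    abs_w = np.abs(ranked.scores) ** weight_exponent

    observed: List[Tuple[GeneSet, float, Set[str]]] = []
    perm_es_all: List[np.ndarray] = []
    for gs in sets:
        es, _, leading = enrichment_score(ranked, gs, weight_exponent)
        n_hits = sum(1 for g in ranked.genes if g in gs.genes)
        observed.append((gs, es, leading))
        perm_es_all.append(_permutation_es(abs_w, n_hits, n_perm, rng))

    results: List[EnrichmentResult] = []
    obs_nes = np.empty(len(sets))
    perm_nes_all: List[np.ndarray] = []
    for i, ((gs, es, leading), perm) in enumerate(zip(observed, perm_es_all)):
        pos = perm[perm >= 0]
        neg = perm[perm < 0]
        if es >= 0:
            same = pos
            n_extreme = int((same >= es).sum())
        else:
            same = neg
            n_extreme = int((same <= es).sum())
        p = (1 + n_extreme) / (len(same) + 1)
        pos_mean = pos.mean() if pos.size else np.nan
        neg_mean = -neg.mean() if neg.size else np.nan
        denom = pos_mean if es >= 0 else neg_mean
        if not np.isfinite(denom) or denom == 0:
            denom = float(np.abs(perm).mean()) or 1.0
        nes = es / denom
        perm_nes = np.where(perm >= 0,
                            perm / (pos_mean if np.isfinite(pos_mean) and pos_mean else 1.0),
                            perm / (neg_mean if np.isfinite(neg_mean) and neg_mean else 1.0))
        obs_nes[i] = nes
        perm_nes_all.append(perm_nes)
        results.append(EnrichmentResult(gs.name, es, float(nes), float(p), np.nan, leading))

    pooled = np.concatenate(perm_nes_all)
    pooled_pos = pooled[pooled >= 0]
    pooled_neg = pooled[pooled < 0]
    nes_pos = obs_nes[obs_nes >= 0]
    nes_neg = obs_nes[obs_nes < 0]
    for res in results:
        nes = res.nes
        if nes >= 0:
            num = (pooled_pos >= nes).mean() if pooled_pos.size else 0.0
            den = (nes_pos >= nes).mean() if nes_pos.size else 1.0
        else:
            num = (pooled_neg <= nes).mean() if pooled_neg.size else 0.0
            den = (nes_neg <= nes).mean() if nes_neg.size else 1.0
        res.fdr = float(min(1.0, num / den)) if den > 0 else 1.0
    return results


def pathway_carrier_summary(
    variants: Iterable[VariantCall], pathway: GeneSet, n_samples: int
) -> Tuple[int, float, int, float]:
    """Carrier and mutual-exclusivity summary of one pathway.

    Returns ``(n_carriers, frequency_percent, n_mutations,
    exclusivity_fraction)``: distinct samples with at least one non-silent
    mutation in a pathway gene, that count as a one-decimal percentage of the
    cohort, the number of such mutations, and the fraction of carrier samples
    whose mutations hit exactly one pathway gene.
    """
    hits = [v for v in variants if v.is_non_silent and v.gene_symbol in pathway.genes]
    genes_per_sample: dict = {}
    for v in hits:
        genes_per_sample.setdefault(v.sample_id, set()).add(v.gene_symbol)
    n_carriers = len(genes_per_sample)
    if n_samples < n_carriers:
        raise ValueError(f"n_samples={n_samples} smaller than {n_carriers} observed carriers")
    frequency = round(100.0 * n_carriers / n_samples, 1)
    exclusive = sum(1 for genes in genes_per_sample.values() if len(genes) == 1)
    exclusivity = exclusive / n_carriers if n_carriers else 0.0
    return n_carriers, frequency, len(hits), exclusivity
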