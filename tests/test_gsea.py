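"""Ranking, the weighted KS statistic, permutation GSEA, pathway summaries."""

from __future__ import annotations

import numpy as np
import pytest

from nbexome import (
    GeneDriverSummary,
    GeneSet,
    RankedGeneList,
    enrichment_score,
    gsea_preranked,
    pathway_carrier_summary,
    rank_genes,
)
from nbexome.gsea import _permutation_es

from .conftest import make_call


def _summary(gene, chasm_p):
    return GeneDriverSummary(
        gene_symbol=gene, n_nonsilent_mutations=1, n_carrier_samples=1,
        carrier_frequency=0.01, chasm_gene_p=chasm_p, vest_gene_p=chasm_p,
    )


def _brute_force_es(genes, scores, members, weight):
    """Sequential textbook running sum, independent of the implementation."""
    hits = [g in members for g in genes]
    n, n_hits = len(genes), sum(hits)
    denom = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    unweighted = denom == 0
    running, value = [], 0.0
    for g, s, h in zip(genes, scores, hits):
        if h:
            value += (1.0 if unweighted else abs(s) ** weight) / (n_hits if unweighted else denom)
        else:
            value -= 1.0 / (n - n_hits)
        running.append(value)
    return max(running, key=abs)


class TestRankGenes:
    def test_orders_by_pathogenicity(self):
        ranked = rank_genes([_summary("B", 0.1), _summary("A", 0.01)])
        assert ranked.genes == ["A", "B"]
        assert ranked.scores[0] == pytest.approx(2.0)

    def test_ties_break_lexicographically(self):
        ranked = rank_genes([_summary("ZZZ", 0.05), _summary("AAA", 0.05)])
        assert ranked.genes == ["AAA", "ZZZ"]

    def test_invariant_to_input_permutation(self):
        rng = np.random.default_rng(6)
        summaries = [_summary(f"G{i:03d}", p) for i, p in enumerate(rng.random(50))]
        ranked = rank_genes(summaries)
        shuffled = list(summaries)
        rng.shuffle(shuffled)
        again = rank_genes(shuffled)
        assert ranked.genes == again.genes
        np.testing.assert_array_equal(ranked.scores, again.scores)


class TestEnrichmentScore:
    def _ranked(self, scores):
        return RankedGeneList(
            genes=[f"G{i:02d}" for i in range(len(scores))],
            scores=np.asarray(scores, dtype=float),
        )

    def test_top_block_unweighted_matches_brute_force(self):
        ranked = self._ranked(np.linspace(10, 1, 10))
        members = frozenset(ranked.genes[:3])
        es, _, leading = enrichment_score(ranked, GeneSet("top", members), 0.0)
        expected = _brute_force_es(ranked.genes, ranked.scores, members, 0.0)
        assert es == pytest.approx(expected)
        assert es == pytest.approx(1.0)  # 3 consecutive hits from rank 1
        assert leading == members

    def test_bottom_half_set_scores_negative(self):
        ranked = self._ranked(np.linspace(10, 1, 10))
        es, _, _ = enrichment_score(ranked, GeneSet("bottom", ranked.genes[5:]), 0.0)
        assert es < 0

    def test_all_memberships_n8_match_brute_force_exactly(self):
        rng = np.random.default_rng(13)
        scores = np.sort(rng.random(8))[::-1]
        ranked = self._ranked(scores)
        for weight in (0.0, 1.0, 1.5):
            for bits in range(1, 2 ** 8):
                members = frozenset(
                    g for i, g in enumerate(ranked.genes) if bits >> i & 1
                )
                es, _, _ = enrichment_score(ranked, GeneSet("m", members), weight)
                assert es == pytest.approx(
                    _brute_force_es(ranked.genes, scores, members, weight), abs=1e-12
                )

    def test_random_instances_up_to_12_match_brute_force(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            scores = np.sort(rng.random(n))[::-1]
            ranked = self._ranked(scores)
            k = int(rng.integers(1, n + 1))
            members = frozenset(rng.choice(ranked.genes, size=k, replace=False))
            weight = float(rng.choice([0.0, 1.0, 2.0]))
            es, _, _ = enrichment_score(ranked, GeneSet("m", members), weight)
            assert es == pytest.approx(
                _brute_force_es(ranked.genes, scores, members, weight), abs=1e-12
            )

    def test_empty_overlap_names_the_set(self):
        ranked = self._ranked([3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="ABSENT"):
            enrichment_score(ranked, GeneSet("ABSENT", frozenset({"X"})), 1.0)


def test_vectorized_permutation_es_matches_sequential():
    """The batched null-ES computation agrees with the sequential statistic
    on the same memberships."""
    rng = np.random.default_rng(31)
    n, k = 40, 7
    scores = np.sort(rng.random(n))[::-1]
    genes = [f"G{i:02d}" for i in range(n)]
    ranked = RankedGeneList(genes=genes, scores=scores)
    abs_w = np.abs(scores)
    es_batch = _permutation_es(abs_w, k, 50, np.random.default_rng(8))
    positions = np.argsort(np.random.default_rng(8).random((50, n)), axis=1)[:, :k]
    for row, es_value in zip(positions, es_batch):
        members = frozenset(genes[i] for i in row)
        expected = _brute_force_es(genes, scores, members, 1.0)
        assert es_value == pytest.approx(expected, abs=1e-12)


class TestGseaPreranked:
    def _random_ranked(self, n, seed):
        scores = np.sort(np.random.default_rng(seed).random(n))[::-1]
        return RankedGeneList([f"G{i:03d}" for i in range(n)], scores)

    def test_same_seed_gives_identical_results(self):
        ranked = self._random_ranked(100, 0)
        sets = [GeneSet(f"S{i}", frozenset(f"G{j:03d}" for j in range(i, i + 10)))
                for i in range(5)]
        a = gsea_preranked(ranked, sets, n_perm=200, seed=5)
        b = gsea_preranked(ranked, sets, n_perm=200, seed=5)
        assert [(r.set_name, r.es, r.nes, r.p_perm, r.fdr) for r in a] == [
            (r.set_name, r.es, r.nes, r.p_perm, r.fdr) for r in b
        ]

    def test_p_value_never_zero(self):
        ranked = self._random_ranked(200, 1)
        planted = GeneSet("planted", frozenset(ranked.genes[:15]))
        (res,) = gsea_preranked(ranked, [planted], n_perm=500, seed=2)
        assert res.p_perm >= 1 / 501
        assert res.p_perm <= 0.01

    def test_oversized_set_rejected(self):
        ranked = self._random_ranked(5, 3)
        big = GeneSet("big", frozenset(list(ranked.genes) + ["EXTRA"]))
        with pytest.raises(ValueError, match="larger"):
            gsea_preranked(ranked, [big], n_perm=100, seed=0)

    def test_null_nes_magnitude_centered_at_one(self):
        ranked = self._random_ranked(150, 4)
        rng = np.random.default_rng(7)
        sets = [
            GeneSet(f"R{i}", frozenset(rng.choice(ranked.genes, size=12, replace=False)))
            for i in range(200)
        ]
        results = gsea_preranked(ranked, sets, n_perm=150, seed=11)
        mean_abs_nes = float(np.mean([abs(r.nes) for r in results]))
        assert mean_abs_nes == pytest.approx(1.0, abs=0.1)


class TestPathwayCarrierSummary:
    def _pathway_cohort(self):
        pathway = GeneSet("FA_RAC", frozenset(f"PW{i:02d}" for i in range(13)))
        variants = []
        pos = 1
        # 12 samples with one pathway gene each; 2 samples with >1 gene
        for i in range(12):
            variants.append(make_call(sample_id=f"S{i:02d}", pos=pos,
                                      gene_symbol=f"PW{i % 13:02d}"))
            pos += 1
        for i, genes in ((12, ("PW00", "PW01", "PW02", "PW03")),
                         (13, ("PW04", "PW05", "PW06", "PW07"))):
            for g in genes:
                variants.append(make_call(sample_id=f"S{i:02d}", pos=pos, gene_symbol=g))
                pos += 1
        return variants, pathway

    def test_fourteen_of_ninety_nine_reports_14_1_percent(self):
        variants, pathway = self._pathway_cohort()
        n_carriers, frequency, n_mutations, _ = pathway_carrier_summary(
            variants, pathway, n_samples=99
        )
        assert n_carriers == 14
        assert frequency == 14.1
        assert n_mutations == 20

    def test_exclusivity_counts_single_gene_carriers(self):
        variants, pathway = self._pathway_cohort()
        *_, exclusivity = pathway_carrier_summary(variants, pathway, 99)
        assert exclusivity == pytest.approx(12 / 14)

    def test_double_hit_sample_is_not_exclusive(self):
        variants = [
            make_call(sample_id="S1", pos=1, gene_symbol="PW1"),
            make_call(sample_id="S1", pos=2, gene_symbol="PW2"),
        ]
        pathway = GeneSet("P", frozenset({"PW1", "PW2"}))
        n_carriers, _, _, exclusivity = pathway_carrier_summary(variants, pathway, 10)
        assert n_carriers == 1 and exclusivity == 0.0

    def test_non_pathway_and_silent_mutations_ignored(self):
        variants = [
            make_call(sample_id="S1", pos=1, gene_symbol="OTHER"),
            make_call(sample_id="S2", pos=2, gene_symbol="PW1", functional_class="silent"),
        ]
        pathway = GeneSet("P", frozenset({"PW1"}))
        n_carriers, frequency, n_mutations, _ = pathway_carrier_summary(variants, pathway, 10)
        assert (n_carriers, frequency, n_mutations) == (0, 0.0, 0)
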