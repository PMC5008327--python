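"""Context canonicalization, spectrum construction and exposure fitting."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbexome import (
    CONTEXT_LABELS,
    CohortSpec,
    SignatureMatrix,
    Spectrum96,
    build_spectrum,
    canonical_context,
    class_fractions,
    cosine_similarity,
    decompose,
    simulate_somatic_variants,
)
from nbexome.types import COMPLEMENT, revcomp

from .conftest import make_call

BASES = "ACGT"


class TestCanonicalContext:
    def test_purine_reference_is_reverse_complemented(self):
        # G>T in A_G_C lies on the purine strand; its pyrimidine-strand
        # equivalent is C>A in revcomp(AGC) = G_C_T.
        assert CONTEXT_LABELS[canonical_context("G", "T", "AGC")] == "G[C>A]T"

    def test_pyrimidine_reference_kept_as_is(self):
        assert CONTEXT_LABELS[canonical_context("C", "T", "GCG")] == "G[C>T]G"

    def test_all_192_strand_class_combinations_cover_96_classes_twice(self):
        hits = {}
        for ref in BASES:
            for alt in BASES:
                if alt == ref:
                    continue
                for five, three in itertools.product(BASES, repeat=2):
                    idx = canonical_context(ref, alt, five + ref + three)
                    hits[idx] = hits.get(idx, 0) + 1
        assert set(hits) == set(range(96))
        assert all(count == 2 for count in hits.values())

    @given(
        ref=st.sampled_from("CT"),
        alt=st.sampled_from(BASES),
        five=st.sampled_from(BASES),
        three=st.sampled_from(BASES),
    )
    @settings(derandomize=True, max_examples=96)
    def test_reverse_complement_input_maps_to_same_class(self, ref, alt, five, three):
        if alt == ref:
            return
        ctx = five + ref + three
        direct = canonical_context(ref, alt, ctx)
        flipped = canonical_context(COMPLEMENT[ref], COMPLEMENT[alt], revcomp(ctx))
        assert direct == flipped

    def test_bad_context_rejected(self):
        with pytest.raises(ValueError):
            canonical_context("C", "A", "ANA")
        with pytest.raises(ValueError):
            canonical_context("C", "A", "AC")
        with pytest.raises(ValueError, match="neither"):
            canonical_context("C", "A", "AAA")


class TestBuildSpectrum:
    def test_empty_list_gives_zero_vector(self):
        assert build_spectrum([]).total == 0

    def test_ten_copies_of_one_class(self):
        calls = [make_call(pos=1000 + i, ref_allele="C", alt_allele="A",
                           trinucleotide_context="ACA") for i in range(10)]
        spec = build_spectrum(calls)
        assert spec.counts[CONTEXT_LABELS.index("A[C>A]A")] == 10
        assert spec.total == 10

    def test_totals_match_simulator_snv_count(self, small_cohort):
        _, variants = small_cohort
        spec = build_spectrum(variants)
        assert spec.total == sum(1 for v in variants if v.variant_class == "SNV")

    def test_snv_without_context_is_an_error(self):
        bad = make_call(trinucleotide_context=None)
        with pytest.raises(ValueError, match="lack"):
            build_spectrum([bad])


class TestClassFractions:
    def test_inferred_cohort_counts_reproduce_reported_percentages(self):
        # 64 C>A and 84 C>T of 228 SNVs give the published 28.07% / 36.84%.
        counts = np.zeros(96, dtype=int)
        counts[CONTEXT_LABELS.index("T[C>A]T")] = 64
        counts[CONTEXT_LABELS.index("G[C>T]G")] = 84
        counts[CONTEXT_LABELS.index("A[T>C]A")] = 80
        fracs = class_fractions(Spectrum96(counts))
        assert round(100 * fracs["C>A"], 2) == 28.07
        assert round(100 * fracs["C>T"], 2) == 36.84

    def test_uniform_spectrum_gives_one_sixth_each(self):
        fracs = class_fractions(Spectrum96(np.ones(96, dtype=int)))
        np.testing.assert_allclose(list(fracs.values()), 1 / 6)

    def test_single_bin_spectrum_is_all_one_class(self):
        counts = np.zeros(96, dtype=int)
        counts[5] = 3
        assert class_fractions(Spectrum96(counts))["C>A"] == 1.0

    @given(scale=st.integers(min_value=1, max_value=1000), seed=st.integers(0, 100))
    @settings(derandomize=True, max_examples=25)
    def test_invariant_under_count_scaling(self, scale, seed):
        counts = np.random.default_rng(seed).integers(0, 50, size=96)
        if counts.sum() == 0:
            counts[0] = 1
        base = class_fractions(Spectrum96(counts))
        scaled = class_fractions(Spectrum96(counts * scale))
        np.testing.assert_allclose(list(base.values()), list(scaled.values()))

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            class_fractions(Spectrum96(np.zeros(96, dtype=int)))


class TestCosineSimilarity:
    def test_identical_spectra_give_one(self):
        counts = np.random.default_rng(0).integers(0, 20, 96)
        spec = Spectrum96(counts + 1)
        assert cosine_similarity(spec, spec) == pytest.approx(1.0)

    def test_disjoint_support_gives_zero(self):
        a = np.zeros(96); a[:48] = 1
        b = np.zeros(96); b[48:] = 1
        assert cosine_similarity(Spectrum96(a), Spectrum96(b)) == 0.0

    def test_matches_direct_dot_product_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = rng.integers(0, 100, 96).astype(float)
            b = rng.integers(0, 100, 96).astype(float)
            a[0] += 1; b[-1] += 1
            fa, fb = a / a.sum(), b / b.sum()
            expected = float(np.dot(fa, fb) / np.sqrt(np.dot(fa, fa) * np.dot(fb, fb)))
            got = cosine_similarity(Spectrum96(a), Spectrum96(b))
            assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(Spectrum96(np.zeros(96)), Spectrum96(np.ones(96)))


def _grid_search_two_profile(freqs: np.ndarray, profiles: np.ndarray, step: float = 1e-3):
    """Brute-force simplex search for the best 2-signature mixture."""
    ws = np.arange(0.0, 1.0 + step / 2, step)
    mixes = np.outer(ws, profiles[:, 0]) + np.outer(1 - ws, profiles[:, 1])
    errs = np.linalg.norm(mixes - freqs, axis=1)
    best = int(np.argmin(errs))
    return ws[best], errs[best]


class TestDecompose:
    def test_exact_reference_recovered_with_zero_residual(self):
        rng = np.random.default_rng(3)
        profiles = rng.dirichlet(np.ones(96), size=3).T
        refs = SignatureMatrix(["s1", "s2", "s3"], profiles)
        spec = Spectrum96(profiles[:, 1] * 10_000)
        exp = decompose(spec, refs)
        assert exp.weights["s2"] == pytest.approx(1.0, abs=1e-8)
        assert exp.residual_norm == pytest.approx(0.0, abs=1e-8)

    def test_two_profile_toy_matches_simplex_grid_search(self):
        # A 4-bin sub-problem embedded in the 96-bin space.
        profiles = np.zeros((96, 2))
        profiles[0:4, 0] = [0.5, 0.3, 0.15, 0.05]
        profiles[0:4, 1] = [0.05, 0.15, 0.3, 0.5]
        refs = SignatureMatrix(["a", "b"], profiles)
        rng = np.random.default_rng(21)
        for true_w in (0.25, 0.5, 0.8):
            mix = true_w * profiles[:, 0] + (1 - true_w) * profiles[:, 1]
            counts = rng.multinomial(20_000, mix)
            exp = decompose(Spectrum96(counts), refs)
            w_grid, _ = _grid_search_two_profile(counts / counts.sum(), profiles)
            assert exp.weights["a"] == pytest.approx(w_grid, abs=2e-3)

    def test_mixture_recovery_within_two_percent(self):
        rng = np.random.default_rng(17)
        profiles = np.column_stack([
            rng.dirichlet(np.ones(96)),
            rng.dirichlet(np.ones(96)),
        ])
        refs = SignatureMatrix(["a", "b"], profiles)
        mix = 0.6 * profiles[:, 0] + 0.4 * profiles[:, 1]
        counts = rng.multinomial(50_000, mix)
        exp = decompose(Spectrum96(counts), refs)
        assert exp.weights["a"] == pytest.approx(0.6, abs=0.02)

    def test_residual_not_worse_than_any_single_signature_fit(self):
        rng = np.random.default_rng(29)
        profiles = rng.dirichlet(np.ones(96), size=4).T
        refs = SignatureMatrix(list("wxyz"), profiles)
        counts = rng.multinomial(5_000, rng.dirichlet(np.ones(96)))
        spec = Spectrum96(counts)
        exp = decompose(spec, refs)
        freqs = spec.frequencies()
        for j in range(4):
            # best scaled single-profile fit (vertex of the cone)
            scale = max(0.0, float(freqs @ profiles[:, j] / (profiles[:, j] @ profiles[:, j])))
            vertex_resid = np.linalg.norm(freqs - scale * profiles[:, j])
            assert exp.residual_norm <= vertex_resid + 1e-12

    def test_all_zero_profile_rejected(self):
        profiles = np.zeros((96, 1))
        with pytest.raises(ValueError):
            SignatureMatrix(["z"], profiles)
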