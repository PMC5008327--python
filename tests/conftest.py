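"""Shared fixtures: small programmatically built cohorts and helpers."""

from __future__ import annotations

import pytest

from nbexome import CohortSpec, VariantCall, simulate_somatic_variants


def make_call(**overrides) -> VariantCall:
    """A valid missense SNV with sensible read support; override freely."""
    fields = dict(
        sample_id="NB001",
        chrom="chr1",
        pos=1_000_000,
        ref_allele="C",
        alt_allele="A",
        variant_class="SNV",
        functional_class="missense",
        gene_symbol="GENE1",
        tumor_depth=100,
        tumor_alt_count=40,
        normal_depth=100,
        normal_alt_count=0,
        dbsnp_member=False,
        trinucleotide_context="ACA",
    )
    fields.update(overrides)
    return VariantCall(**fields)


@pytest.fixture(scope="session")
def small_cohort():
    """A 17-pair simulated cohort at the default mutation load."""
    spec = CohortSpec(rng_seed=42)
    return spec, simulate_somatic_variants(spec)
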