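"""Seeded synthetic-cohort generator for every input the pipeline consumes.

Emulates a tumor/normal exome cohort with the statistical structure the
downstream analysis assumes: per-sample somatic mutation counts are Poisson
with a configurable mean (default 17, a typical non-silent load per
aggressive neuroblastoma exome), trinucleotide-context classes are drawn
from a mixture of signature profiles, tumor variant allele fractions follow
Beta(8, 12) (clonal mutations in ~75%-pure tumors), and normal alt counts
are near zero.  Pathogenicity scores are Uniform(0,1) for passengers and
Beta-concentrated near zero for planted driver genes; germline carrier
tables are Binomial draws from per-cohort carrier frequencies.

Everything is a pure function of (spec, seed): per-sample randomness comes
from sub-streams derived by stably hashing the sample id together with the
global seed, so output does not depend on iteration order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .burden import BurdenRow
from .spectrum import CONTEXT_LABELS, SignatureMatrix
from .types import VariantCall

#: Mixture of functional classes among simulated non-silent mutations.
_FUNCTIONAL_MIX = (
    ("missense", 0.72),
    ("nonsense", 0.08),
    ("splice_site", 0.06),
    ("frameshift_indel", 0.09),
    ("inframe_indel", 0.05),
)

#: A long-tail passenger universe: with ~17 mutations per exome, a cohort's
#: mutations scatter thinly over thousands of genes, most hit once or twice.
_DEFAULT_PASSENGERS = tuple(f"PSG{i:04d}" for i in range(1, 2001))


def default_signatures() -> SignatureMatrix:
    """Two synthetic, well-separated reference signatures.

    ``deamination_like`` concentrates on C>T at NpCpG sites (the ubiquitous
    5-methylcytosine deamination process); ``c_to_a_like`` concentrates on
    C>A, strongest in TpCpT contexts (the transversion-heavy process seen in
    neuroblastoma).  Both are synthetic profiles built for simulation and
    testing, not published signature estimates.
    """
    labels = np.array(CONTEXT_LABELS)
    deam = np.full(96, 1e-4)
    for i, lab in enumerate(labels):
        if "[C>T]" in lab:
            deam[i] = 4.0 if lab.endswith("G") else 1.0
    c_to_a = np.full(96, 1e-4)
    for i, lab in enumerate(labels):
        if "[C>A]" in lab:
            c_to_a[i] = 4.0 if lab.startswith("T") and lab.endswith("T") else 1.0
    profiles = np.column_stack([deam / deam.sum(), c_to_a / c_to_a.sum()])
    return SignatureMatrix(["deamination_like", "c_to_a_like"], profiles)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic tumor/normal cohort."""

    n_tumor_normal_pairs: int = 17
    mean_mutations_per_sample: float = 17.0
    signature_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"deamination_like": 0.55, "c_to_a_like": 0.45}
    )
    driver_genes: Mapping[str, float] = field(default_factory=dict)
    passenger_gene_pool: Sequence[str] = _DEFAULT_PASSENGERS
    driver_score_beta: Tuple[float, float] = (1.0, 50.0)
    case_control_carrier_freqs: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_tumor_normal_pairs < 1:
            raise ValueError("need at least one tumor/normal pair")
        if self.mean_mutations_per_sample <= 0:
            raise ValueError("mean_mutations_per_sample must be positive")
        if not self.signature_mixture:
            raise ValueError("signature_mixture is empty")
        weights = np.array(list(self.signature_mixture.values()), dtype=float)
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-8:
            raise ValueError("signature_mixture weights must be non-negative and sum to 1")
        for gene, p in self.driver_genes.items():
            if not (0 <= p <= 1):
                raise ValueError(f"driver probability for {gene} outside [0, 1]")
        for gene, cohorts in self.case_control_carrier_freqs.items():
            for cohort, p in cohorts.items():
                if not (0 <= p <= 1):
                    raise ValueError(f"carrier frequency {gene}/{cohort} outside [0, 1]")
        if not self.passenger_gene_pool:
            raise ValueError("passenger_gene_pool is empty")


def _sample_rng(seed: int, sample_id: str, stream: str = "") -> np.random.Generator:
    """Sub-stream for one sample, independent of insertion order."""
    tag = zlib.crc32(f"{sample_id}/{stream}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, tag]))


def _draw_variant(
    sample_id: str,
    gene: str,
    serial: int,
    bin_index: int,
    rng: np.random.Generator,
    functional_class: str,
) -> VariantCall:
    label = CONTEXT_LABELS[bin_index]
    five, sub, three = label[0], label[2:5], label[6]
    ref, alt = sub[0], sub[2]
    context = five + ref + three
    if functional_class in ("frameshift_indel", "inframe_indel"):
        if rng.random() < 0.5:
            vclass, ref_a, alt_a = "deletion", ref + context[2], ref
        else:
            vclass, ref_a, alt_a = "insertion", ref, ref + "A"
        ctx: Optional[str] = None
    else:
        vclass, ref_a, alt_a, ctx = "SNV", ref, alt, context
    vaf = rng.beta(8, 12)
    tumor_depth = max(int(rng.poisson(110)), 8)
    tumor_alt = min(int(rng.binomial(tumor_depth, vaf)), tumor_depth)
    normal_depth = max(int(rng.poisson(110)), 8)
    normal_alt = min(int(rng.binomial(normal_depth, 0.001)), normal_depth)
    return VariantCall(
        sample_id=sample_id,
        chrom=f"chr{1 + serial % 22}",
        pos=1_000_000 + serial * 1_000 + int(rng.integers(0, 1_000)),
        ref_allele=ref_a,
        alt_allele=alt_a,
        variant_class=vclass,
        functional_class=functional_class,
        gene_symbol=gene,
        tumor_depth=tumor_depth,
        tumor_alt_count=max(tumor_alt, 4),
        normal_depth=normal_depth,
        normal_alt_count=normal_alt,
        dbsnp_member=False,
        trinucleotide_context=ctx,
    )


def simulate_somatic_variants(
    spec: CohortSpec, signatures: Optional[SignatureMatrix] = None
) -> List[VariantCall]:
    """Simulate the cohort's somatic variant calls.

    Per sample, a Poisson(mean) number of passenger mutations is drawn from
    the passenger gene pool, plus one mutation per planted driver gene with
    its per-sample probability.  Context classes come from the signature
    mixture; indel classes carry no context.
    """
    spec.validate()
    if signatures is None:
        signatures = default_signatures()
    missing = [s for s in spec.signature_mixture if s not in signatures.signature_names]
    if missing:
        raise ValueError(f"signature_mixture names not in the signature matrix: {missing}")
    sig_names = list(spec.signature_mixture)
    sig_weights = np.array([spec.signature_mixture[s] for s in sig_names])
    profiles = np.column_stack([signatures.profile(s) for s in sig_names])
    fclasses = [c for c, _ in _FUNCTIONAL_MIX]
    fweights = np.array([w for _, w in _FUNCTIONAL_MIX])

    variants: List[VariantCall] = []
    for i in range(spec.n_tumor_normal_pairs):
        sample_id = f"NB{i + 1:03d}"
        rng = _sample_rng(spec.rng_seed, sample_id, "somatic")
        n_passenger = rng.poisson(spec.mean_mutations_per_sample)
        genes = list(rng.choice(list(spec.passenger_gene_pool), size=n_passenger))
        for gene, p in sorted(spec.driver_genes.items()):
            if rng.random() < p:
                genes.append(gene)
        for serial, gene in enumerate(genes):
            sig = rng.choice(len(sig_names), p=sig_weights)
            bin_index = int(rng.choice(96, p=profiles[:, sig]))
            is_driver = gene in spec.driver_genes
            fclass = (
                "missense" if is_driver else str(rng.choice(fclasses, p=fweights))
            )
            variants.append(_draw_variant(sample_id, str(gene), serial, bin_index, rng, fclass))
    return variants


def simulate_pathogenicity_scores(
    variants: Iterable[VariantCall], spec: CohortSpec
) -> pd.DataFrame:
    """CHASM-style and VEST-style p-values for every non-silent variant.

    Passenger scores are Uniform(0, 1); mutations in planted driver genes
    draw from Beta(driver_score_beta), concentrated near zero.
    """
    spec.validate()
    a, b = spec.driver_score_beta
    rows = []
    seen = set()
    for v in variants:
        if not v.is_non_silent:
            continue
        if v.key in seen:
            raise ValueError(f"duplicate variant key {v.key}")
        seen.add(v.key)
        rng = _sample_rng(spec.rng_seed, "/".join(map(str, v.key)), "scores")
        if v.gene_symbol in spec.driver_genes:
            chasm_p, vest_p = rng.beta(a, b), rng.beta(a, b)
        else:
            chasm_p, vest_p = rng.random(), rng.random()
        rows.append(
            dict(zip(("sample_id", "chrom", "pos", "ref_allele", "alt_allele"), v.key))
            | {"chasm_p": float(chasm_p), "vest_p": float(vest_p)}
        )
    columns = ["sample_id", "chrom", "pos", "ref_allele", "alt_allele", "chasm_p", "vest_p"]
    return pd.DataFrame(rows, columns=columns)


def planted_cohort(seed: int = 0) -> Tuple["CohortSpec", list, Dict[str, int]]:
    """A full input set with planted structure for end-to-end validation.

    Returns ``(spec, gene_sets, cohort_sizes)``:

    * one strongly mutated driver gene (``DRIVER1``, per-sample probability
      0.22, driver-like scores) that the dual FDR gate should flag;
    * six moderately mutated pathway genes collected in the
      ``PLANTED_PATHWAY`` gene set (plus decoy sets of passengers) that
      pre-ranked GSEA should rank first;
    * one germline burden gene (``BURDEN1``, case carrier frequency 0.15 vs
      0.002 in controls) that should have the smallest combined p.
    """
    from .types import GeneSet

    pathway_genes = [f"FA{i:02d}" for i in range(12)]
    driver_genes: Dict[str, float] = {"DRIVER1": 0.22}
    for g in pathway_genes[:6]:
        driver_genes[g] = 0.08
    burden_freqs: Dict[str, Dict[str, float]] = {
        "BURDEN1": {"case": 0.15, "ctrl_a": 0.002, "ctrl_b": 0.002}
    }
    for i in range(10):
        burden_freqs[f"NULLG{i:02d}"] = {"case": 0.01, "ctrl_a": 0.01, "ctrl_b": 0.01}
    spec = CohortSpec(
        n_tumor_normal_pairs=99,
        mean_mutations_per_sample=17.0,
        driver_genes=driver_genes,
        case_control_carrier_freqs=burden_freqs,
        rng_seed=seed,
    )
    rng = np.random.default_rng(seed)
    passengers = list(spec.passenger_gene_pool)
    gene_sets = [GeneSet("PLANTED_PATHWAY", frozenset(pathway_genes))]
    for i in range(15):
        members = rng.choice(passengers, size=12, replace=False)
        gene_sets.append(GeneSet(f"DECOY{i:02d}", frozenset(str(g) for g in members)))
    cohort_sizes = {"case": 52, "ctrl_a": 107, "ctrl_b": 502}
    return spec, gene_sets, cohort_sizes


def simulate_carrier_tables(
    spec: CohortSpec, cohort_sizes: Mapping[str, int]
) -> List[BurdenRow]:
    """Binomial per-gene carrier counts for the case cohort (named ``case``)
    and every control cohort in ``cohort_sizes``."""
    spec.validate()
    if "case" not in cohort_sizes:
        raise ValueError("cohort_sizes must include a 'case' cohort")
    if any(n <= 0 for n in cohort_sizes.values()):
        raise ValueError("cohort sizes must be positive")
    rows: List[BurdenRow] = []
    for gene in sorted(spec.case_control_carrier_freqs):
        freqs = spec.case_control_carrier_freqs[gene]
        missing = [c for c in cohort_sizes if c not in freqs]
        if missing:
            raise ValueError(f"gene {gene} missing carrier frequency for cohorts {missing}")
        rng = _sample_rng(spec.rng_seed, gene, "carriers")
        counts = {}
        for cohort in sorted(cohort_sizes):
            size = cohort_sizes[cohort]
            with_ = int(rng.binomial(size, freqs[cohort]))
            counts[cohort] = (with_, size - with_)
        case_with, case_without = counts.pop("case")
        rows.append(BurdenRow(gene, case_with, case_without, counts))
    return rows
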