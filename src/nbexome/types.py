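"""Core domain types shared across the pipeline.

A :class:`VariantCall` is one called variant in one tumor/normal pair,
carrying the allele-count evidence the somatic filter needs and the
annotation fields (gene, functional class, trinucleotide context, dbSNP
membership) that downstream stages consume.  Coordinates are 1-based and
fully closed, as in VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VARIANT_CLASSES = frozenset({"SNV", "insertion", "deletion"})

FUNCTIONAL_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "splice_site",
        "frameshift_indel",
        "inframe_indel",
        "silent",
        "noncoding",
    }
)

#: Classes counted as "non-silent" throughout: the protein-affecting classes
#: displayed in per-sample mutation summaries; silent and noncoding excluded.
NON_SILENT_CLASSES = frozenset(
    {"missense", "nonsense", "splice_site", "frameshift_indel", "inframe_indel"}
)

_DNA = frozenset("ACGT")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class VariantCall:
    """One called variant with its tumor/normal read support and annotation."""

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: str
    functional_class: str
    gene_symbol: str
    tumor_depth: int
    tumor_alt_count: int
    normal_depth: int
    normal_alt_count: int
    dbsnp_member: bool = False
    trinucleotide_context: Optional[str] = None

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(f"unknown functional_class {self.functional_class!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        if not (0 <= self.tumor_alt_count <= self.tumor_depth):
            raise ValueError(
                f"tumor_alt_count {self.tumor_alt_count} outside [0, depth={self.tumor_depth}]"
            )
        if not (0 <= self.normal_alt_count <= self.normal_depth):
            raise ValueError(
                f"normal_alt_count {self.normal_alt_count} outside [0, depth={self.normal_depth}]"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele equals alt_allele")
        if self.variant_class == "SNV":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("SNV alleles must have length 1")
            if self.ref_allele not in _DNA or self.alt_allele not in _DNA:
                raise ValueError("SNV alleles must be A/C/G/T")
        ctx = self.trinucleotide_context
        if ctx is not None:
            if len(ctx) != 3 or any(b not in _DNA for b in ctx):
                raise ValueError(f"trinucleotide_context must be 3 bases of ACGT, got {ctx!r}")
            if self.variant_class == "SNV" and ctx[1] not in (
                self.ref_allele,
                COMPLEMENT[self.ref_allele],
            ):
                raise ValueError(
                    f"context {ctx!r} center does not match ref {self.ref_allele!r} or its complement"
                )

    @property
    def key(self) -> tuple:
        """Unique identity of a mutation within the cohort."""
        return (self.sample_id, self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt_count / self.tumor_depth if self.tumor_depth else 0.0

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt_count / self.normal_depth if self.normal_depth else 0.0

    @property
    def is_non_silent(self) -> bool:
        return self.functional_class in NON_SILENT_CLASSES


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols, e.g. one KEGG pathway."""

    name: str
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)
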