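"""96-context mutation spectra and signature exposure fitting.

Somatic SNVs are binned into 96 classes: 6 pyrimidine-reference substitution
classes (C>A, C>G, C>T, T>A, T>C, T>G) times 16 flanking-base combinations.
Mutations reported on the purine strand are reverse-complemented onto the
pyrimidine strand, so e.g. G>T in context A*G*C is counted as C>A in G*C*T,
labelled ``G[C>A]T`` in the COSMIC convention.

An observed spectrum is modelled as a non-negative mixture of reference
signature profiles; exposures are fit by non-negative least squares on the
frequency-normalized spectrum and reported renormalized to sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import nnls

from .types import COMPLEMENT, VariantCall, revcomp

logger = logging.getLogger(__name__)

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: Canonical 96-bin order: substitution class major, then 5' base, then 3' base.
CONTEXT_LABELS: tuple = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in _BASES
    for three in _BASES
)

_LABEL_INDEX = {label: i for i, label in enumerate(CONTEXT_LABELS)}


def context_label(index: int) -> str:
    return CONTEXT_LABELS[index]


def canonical_context(ref: str, alt: str, context: str) -> int:
    """Map a single-base substitution with its trinucleotide context to the
    canonical class index in 0..95.

    Purine-reference mutations (ref G or A) are reverse-complemented so the
    mutated base is always a pyrimidine (C or T).
    """
    if len(context) != 3 or any(b not in _BASES for b in context):
        raise ValueError(f"context must be 3 bases over ACGT, got {context!r}")
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"ref/alt must be single bases, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref equals alt")
    if context[1] == ref:
        pass
    elif context[1] == COMPLEMENT[ref]:
        # context given on the opposite strand
        context = revcomp(context)
    else:
        raise ValueError(f"context {context!r} center matches neither {ref!r} nor its complement")
    if ref in "GA":
        ref, alt, context = COMPLEMENT[ref], COMPLEMENT[alt], revcomp(context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    return _LABEL_INDEX[label]


@dataclass
class Spectrum96:
    """Ordered 96-bin catalog of somatic SNV counts."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,):
            raise ValueError(f"spectrum must have exactly 96 bins, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("cannot normalize an empty spectrum")
        return self.counts / total


@dataclass
class SignatureMatrix:
    """Reference signature profiles: one probability distribution over the
    96 canonical contexts per signature."""

    signature_names: list
    profiles: np.ndarray  # shape (96, n_signatures), columns sum to 1

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (96, len(self.signature_names)):
            raise ValueError(
                f"profiles shape {self.profiles.shape} does not match "
                f"(96, {len(self.signature_names)})"
            )
        if np.any(self.profiles < 0):
            raise ValueError("signature profiles must be non-negative")
        sums = self.profiles.sum(axis=0)
        bad = [n for n, s in zip(self.signature_names, sums) if abs(s - 1.0) > 1e-8]
        if bad:
            raise ValueError(f"signature profiles do not sum to 1: {bad}")

    def profile(self, name: str) -> np.ndarray:
        return self.profiles[:, self.signature_names.index(name)]


@dataclass
class SignatureExposure:
    """Non-negative per-signature contribution weights (sum to 1) with the
    residual of the least-squares fit."""

    weights: dict
    residual_norm: float


def build_spectrum(variants: Iterable[VariantCall]) -> Spectrum96:
    """Bin the SNVs of a variant list into the 96 canonical classes.

    Non-SNVs are ignored (their count is logged); SNVs lacking a
    trinucleotide context are an error.
    """
    counts = np.zeros(96, dtype=int)
    n_skipped = 0
    missing = []
    for v in variants:
        if v.variant_class != "SNV":
            n_skipped += 1
            continue
        if v.trinucleotide_context is None:
            missing.append(v.key)
            continue
        counts[canonical_context(v.ref_allele, v.alt_allele, v.trinucleotide_context)] += 1
    if missing:
        raise ValueError(f"{len(missing)} SNVs lack trinucleotide context: {missing[:10]}")
    if n_skipped:
        logger.info("build_spectrum: ignored %d non-SNV variants", n_skipped)
    return Spectrum96(counts)


def class_fractions(spectrum: Spectrum96) -> Mapping[str, float]:
    """Fraction of mutations in each of the six substitution classes."""
    if spectrum.total == 0:
        raise ValueError("empty spectrum has no class fractions")
    per_class = spectrum.counts.reshape(6, 16).sum(axis=1)
    fracs = per_class / per_class.sum()
    return dict(zip(SUBSTITUTION_CLASSES, fracs))


def cosine_similarity(a: Spectrum96, b: Spectrum96) -> float:
    """Cosine similarity of two frequency-normalized spectra, in [0, 1]."""
    fa, fb = a.frequencies(), b.frequencies()
    return float(fa @ fb / (np.linalg.norm(fa) * np.linalg.norm(fb)))


def decompose(spectrum: Spectrum96, refs: SignatureMatrix) -> SignatureExposure:
    """Fit non-negative signature exposures to a spectrum.

    Solves ``min_w ||f - P w||_2, w >= 0`` where ``f`` is the
    frequency-normalized spectrum and ``P`` the reference profile matrix,
    then renormalizes the weights to sum to 1.  ``residual_norm`` is the
    minimized objective (before renormalization).
    """
    if np.any(refs.profiles.sum(axis=0) == 0):
        raise ValueError("signature matrix contains an all-zero profile")
    f = spectrum.frequencies()
    w, residual = nnls(refs.profiles, f)
    total = w.sum()
    if total == 0:
        raise ValueError("NNLS returned an all-zero exposure vector")
    weights = {name: float(x) for name, x in zip(refs.signature_names, w / total)}
    return SignatureExposure(weights=weights, residual_norm=float(residual))
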