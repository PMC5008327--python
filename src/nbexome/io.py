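"""Readers and writers for the external formats the pipeline touches.

Three formats with one canonical in-memory representation each:

* variant tables — a list of :class:`~nbexome.types.VariantCall`, read either
  from the package's 14-column MAF-like TSV or from VCF 4.x (tumor/normal
  depths from the DP/AD fields of two named samples; gene symbol, functional
  class and trinucleotide context from the INFO keys ``GENE``, ``FCLASS`` and
  ``CTX``; dbSNP membership from an ``rs``-prefixed ID);
* gene sets — GMT, one tab-separated line per set (name, description,
  members...);
* signature matrices — long-form TSV, 96 rows keyed by COSMIC context label
  with one column per signature.

All writers emit UTF-8 with LF line endings.  Variant tables are positional
(row order preserved); the signature matrix is keyed (row order normalized to
the canonical context order on read).
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, List

import numpy as np

from .spectrum import CONTEXT_LABELS, SignatureMatrix
from .types import GeneSet, VariantCall

logger = logging.getLogger(__name__)

#: Column order of the MAF-like TSV dialect.
MAF_COLUMNS = (
    "sample_id",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "variant_class",
    "functional_class",
    "gene_symbol",
    "tumor_depth",
    "tumor_alt_count",
    "normal_depth",
    "normal_alt_count",
    "dbsnp_member",
    "trinucleotide_context",
)

_INT_FIELDS = {"pos", "tumor_depth", "tumor_alt_count", "normal_depth", "normal_alt_count"}


class FormatError(ValueError):
    """A file failed validation; the message names the offending line."""


def _parse_bool(text: str) -> bool:
    if text in ("1", "true", "True", "TRUE"):
        return True
    if text in ("0", "false", "False", "FALSE"):
        return False
    raise ValueError(f"not a boolean: {text!r}")


def read_variant_table(path, dialect: str = "maf_tsv", *,
                       tumor_sample: str = "TUMOR",
                       normal_sample: str = "NORMAL") -> List[VariantCall]:
    """Read a variant table, validating every record.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"maf_tsv"`` (the package's 14-column TSV) or ``"vcf"``.
    tumor_sample, normal_sample
        Sample names to take tumor/normal depths from (VCF dialect only).
    """
    if dialect == "maf_tsv":
        return _read_maf_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path, tumor_sample, normal_sample)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'maf_tsv' or 'vcf'")


def _read_maf_tsv(path) -> List[VariantCall]:
    records: List[VariantCall] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file (missing header)")
        if tuple(header) != MAF_COLUMNS:
            raise FormatError(
                f"{path}: bad header; expected columns {list(MAF_COLUMNS)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(MAF_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(MAF_COLUMNS)} fields, got {len(row)}"
                )
            fields = dict(zip(MAF_COLUMNS, row))
            try:
                for name in _INT_FIELDS:
                    fields[name] = int(fields[name])
                fields["dbsnp_member"] = _parse_bool(fields["dbsnp_member"])
                ctx = fields["trinucleotide_context"]
                fields["trinucleotide_context"] = ctx if ctx not in ("", ".", "NA") else None
                records.append(VariantCall(**fields))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def _read_vcf(path, tumor_sample: str, normal_sample: str) -> List[VariantCall]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (tumor_sample, normal_sample):
        if name not in samples:
            raise FormatError(f"{path}: sample {name!r} not in VCF samples {samples}")
    t_idx, n_idx = samples.index(tumor_sample), samples.index(normal_sample)
    records: List[VariantCall] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(
                f"{path}: {rec.CHROM}:{rec.POS}: multi-allelic records are not supported"
            )
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) == 1 and len(alt) == 1:
            vclass = "SNV"
        elif len(alt) > len(ref):
            vclass = "insertion"
        else:
            vclass = "deletion"
        depths = rec.format("DP")
        ad = rec.format("AD")
        if depths is None or ad is None:
            raise FormatError(f"{path}: {rec.CHROM}:{rec.POS}: missing DP or AD format field")
        ctx = rec.INFO.get("CTX")
        try:
            records.append(
                VariantCall(
                    sample_id=tumor_sample,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref_allele=ref,
                    alt_allele=alt,
                    variant_class=vclass,
                    functional_class=rec.INFO.get("FCLASS", "noncoding"),
                    gene_symbol=rec.INFO.get("GENE", "."),
                    tumor_depth=int(np.ravel(depths[t_idx])[0]),
                    tumor_alt_count=int(np.ravel(ad[t_idx])[-1]),
                    normal_depth=int(np.ravel(depths[n_idx])[0]),
                    normal_alt_count=int(np.ravel(ad[n_idx])[-1]),
                    dbsnp_member=bool(rec.ID and str(rec.ID).startswith("rs")),
                    trinucleotide_context=ctx,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {rec.CHROM}:{rec.POS}: {exc}") from exc
    return records


def write_variant_table(variants: Iterable[VariantCall], path) -> None:
    """Write variants as the 14-column MAF-like TSV, preserving order."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(MAF_COLUMNS) + "\n")
        for v in variants:
            row = [
                v.sample_id, v.chrom, str(v.pos), v.ref_allele, v.alt_allele,
                v.variant_class, v.functional_class, v.gene_symbol,
                str(v.tumor_depth), str(v.tumor_alt_count),
                str(v.normal_depth), str(v.normal_alt_count),
                "1" if v.dbsnp_member else "0",
                v.trinucleotide_context or ".",
            ]
            fh.write("\t".join(row) + "\n")


def read_gmt(path) -> List[GeneSet]:
    """Read a GMT gene-set collection (name, description, members...)."""
    sets: List[GeneSet] = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            unique = set(members)
            if len(unique) < len(members):
                logger.warning("%s:%d: %d duplicate members in set %r de-duplicated",
                               path, lineno, len(members) - len(unique), name)
            sets.append(GeneSet(name=name, genes=frozenset(unique)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *sorted(gs.genes)]) + "\n")


def read_signature_matrix(path) -> SignatureMatrix:
    """Read a long-form signature TSV: header ``context<TAB>sig1<TAB>...``,
    96 data rows keyed by COSMIC context label in any order.

    Profiles whose column sum is within 1e-3 of 1 are renormalized; larger
    deviations are an error.
    """
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if not header or len(header) < 2:
            raise FormatError(f"{path}: expected header 'context<TAB>signature...'")
        names = header[1:]
        rows = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            label = row[0]
            if label not in CONTEXT_LABELS:
                raise FormatError(f"{path}:{lineno}: unknown context label {label!r}")
            if label in rows:
                raise FormatError(f"{path}:{lineno}: duplicate context label {label!r}")
            if len(row) != len(names) + 1:
                raise FormatError(f"{path}:{lineno}: expected {len(names) + 1} fields")
            try:
                rows[label] = [float(x) for x in row[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    missing = [lab for lab in CONTEXT_LABELS if lab not in rows]
    if missing:
        raise FormatError(f"{path}: missing context rows: {missing}")
    profiles = np.array([rows[lab] for lab in CONTEXT_LABELS], dtype=float)
    sums = profiles.sum(axis=0)
    off = [(n, s) for n, s in zip(names, sums) if not (0.999 <= s <= 1.001)]
    if off:
        raise FormatError(f"{path}: signature column sums outside [0.999, 1.001]: {off}")
    profiles /= sums
    return SignatureMatrix(signature_names=list(names), profiles=profiles)


def write_signature_matrix(matrix: SignatureMatrix, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["context", *matrix.signature_names]) + "\n")
        for i, label in enumerate(CONTEXT_LABELS):
            vals = "\t".join(format(x, ".10g") for x in matrix.profiles[i])
            fh.write(f"{label}\t{vals}\n")
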