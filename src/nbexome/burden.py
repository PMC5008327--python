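"""Case-control rare-variant burden testing in cancer predisposition genes.

Candidate germline variants in a curated predisposition-gene list are
filtered (common dbSNP polymorphisms removed, VEST p < 0.10 kept), per-gene
carrier counts are compared against each control cohort with a two-sided
Fisher's exact test, and a combined p-value is computed by pooling all
control cohorts into a single 2x2 table.  Fold enrichment is the ratio of
case to pooled-control carrier frequency, with a pseudocount guarding the
zero-carrier-control case.

The two-sided p follows the minimum-likelihood rule: the sum of
hypergeometric point probabilities no greater than that of the observed
table, evaluated in log space.  The per-gene carrier counts of the study's
published burden table ship as a packaged fixture (``load_table1_counts``).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import VariantCall

logger = logging.getLogger(__name__)

#: Relative slack when comparing point probabilities to the observed one,
#: absorbing floating-point noise in "as extreme as observed".
_REL_TOL = 1e-7


@dataclass(frozen=True)
class GermlineFilterConfig:
    predisposition_genes: frozenset
    exclude_common_db: bool = True
    vest_p_threshold: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.vest_p_threshold < 1):
            raise ValueError("vest_p_threshold must be in (0, 1)")
        if not self.predisposition_genes:
            raise ValueError("predisposition gene list is empty")


@dataclass
class BurdenRow:
    gene_symbol: str
    case_with: int
    case_without: int
    cohort_counts: Dict[str, Tuple[int, int]]
    cohort_p: Dict[str, float] = field(default_factory=dict)
    combined_p: float = float("nan")
    fold_enrichment: float = float("nan")


def filter_germline_candidates(
    variants: Iterable[VariantCall],
    scores: Mapping[tuple, float],
    config: GermlineFilterConfig,
) -> List[VariantCall]:
    """Keep germline variants that are in a predisposition gene, absent from
    the common-polymorphism database (when enabled), and predicted pathogenic
    (VEST p strictly below the threshold)."""
    variants = list(variants)
    missing = [v.key for v in variants if v.key not in scores]
    if missing:
        raise ValueError(f"{len(missing)} variants lack a VEST score: {missing[:10]}")
    kept = []
    for v in variants:
        if v.gene_symbol not in config.predisposition_genes:
            continue
        if config.exclude_common_db and v.dbsnp_member:
            continue
        if scores[v.key] < config.vest_p_threshold:
            kept.append(v)
    return kept


def _log_hyper_pmf(k: np.ndarray, row1: int, row2: int, col1: int) -> np.ndarray:
    """log P(X = k) for X hypergeometric with margins (row1, row2, col1)."""
    lgamma = math.lgamma

    def logc(n: np.ndarray, r: np.ndarray) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        r = np.asarray(r, dtype=float)
        vec = np.vectorize(lambda a, b: lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1))
        return vec(n, r)

    n = row1 + row2
    return logc(row1, k) + logc(row2, col1 - k) - logc(np.array(n), np.array(col1))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test for the 2x2 table [[a, b], [c, d]].

    The p-value sums hypergeometric point probabilities (over the support of
    tables with the observed margins) that do not exceed the observed table's
    probability, within a small relative tolerance; evaluated in log space.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("table counts must be non-negative")
        if x != int(x):
            raise ValueError("table counts must be integers")
    if a + b + c + d == 0:
        raise ValueError("table is all-zero")
    row1, row2, col1 = a + b, c + d, a + c
    lo, hi = max(0, col1 - row2), min(col1, row1)
    support = np.arange(lo, hi + 1)
    logpmf = _log_hyper_pmf(support, row1, row2, col1)
    log_obs = float(logpmf[support == a][0])
    include = logpmf <= log_obs + math.log1p(_REL_TOL)
    # log-sum-exp over the included tables
    m = logpmf[include].max()
    return float(min(1.0, math.exp(m) * np.exp(logpmf[include] - m).sum()))


def combined_pooled_p(
    case_with: int, case_without: int, cohorts: Sequence[Tuple[int, int]]
) -> float:
    """Combined case-control p: pool all control cohorts by summing their
    carrier/non-carrier counts, then run one two-sided Fisher's exact test."""
    if len(cohorts) == 0:
        raise ValueError("need at least one control cohort")
    pooled_with = sum(w for w, _ in cohorts)
    pooled_without = sum(wo for _, wo in cohorts)
    return fisher_two_sided(case_with, case_without, pooled_with, pooled_without)


def fold_enrichment(
    case_with: int,
    case_without: int,
    pooled_with: int,
    pooled_without: int,
    pseudocount: float = 1.0,
) -> float:
    """Ratio of case carrier frequency to pooled-control carrier frequency.

    The pseudocount is applied to the control carriers only when none were
    observed, keeping the ratio finite.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if case_with == 0:
        raise ValueError("no case carriers; fold enrichment undefined")
    pc = pseudocount if pooled_with == 0 else 0.0
    denom = (pooled_with + pc) / (pooled_with + pooled_without + pc)
    if denom == 0:
        raise ValueError("control carrier frequency is zero; supply a pseudocount")
    return (case_with / (case_with + case_without)) / denom


def burden_report(rows: Iterable[BurdenRow]) -> List[BurdenRow]:
    """Populate per-cohort p, combined p and fold enrichment for every gene
    and return rows sorted by combined p (gene symbol breaking ties)."""
    rows = [
        BurdenRow(r.gene_symbol, r.case_with, r.case_without, dict(r.cohort_counts))
        for r in rows
    ]
    if not rows:
        raise ValueError("no burden rows supplied")
    cohort_names = list(rows[0].cohort_counts)
    for r in rows:
        if set(r.cohort_counts) != set(cohort_names):
            raise ValueError(f"gene {r.gene_symbol} missing counts for some cohorts")
    sizes = {
        name: {r.cohort_counts[name][0] + r.cohort_counts[name][1] for r in rows}
        for name in cohort_names
    }
    for name, distinct in sizes.items():
        if len(distinct) > 1:
            logger.warning("cohort %r has inconsistent sizes across genes: %s", name, sorted(distinct))
    for r in rows:
        for name, (w, wo) in r.cohort_counts.items():
            r.cohort_p[name] = fisher_two_sided(r.case_with, r.case_without, w, wo)
        pairs = [r.cohort_counts[name] for name in cohort_names]
        r.combined_p = combined_pooled_p(r.case_with, r.case_without, pairs)
        pooled_with = sum(w for w, _ in pairs)
        pooled_without = sum(wo for _, wo in pairs)
        if r.case_with > 0:
            r.fold_enrichment = fold_enrichment(
                r.case_with, r.case_without, pooled_with, pooled_without
            )
    rows.sort(key=lambda r: (r.combined_p, r.gene_symbol))
    return rows


def burden_frame(rows: Sequence[BurdenRow]) -> pd.DataFrame:
    """Tabulate a burden report for writing."""
    cohort_names = list(rows[0].cohort_counts) if rows else []
    data: Dict[str, list] = {
        "gene_symbol": [r.gene_symbol for r in rows],
        "case_with": [r.case_with for r in rows],
        "case_without": [r.case_without for r in rows],
    }
    for name in cohort_names:
        data[f"{name}_with"] = [r.cohort_counts[name][0] for r in rows]
        data[f"{name}_without"] = [r.cohort_counts[name][1] for r in rows]
        data[f"{name}_p"] = [r.cohort_p[name] for r in rows]
    data["combined_p"] = [r.combined_p for r in rows]
    data["fold_enrichment"] = [r.fold_enrichment for r in rows]
    return pd.DataFrame(data)


def read_burden_counts(path) -> List[BurdenRow]:
    """Read a carrier-count TSV: columns ``gene, case_with, case_without``
    then ``<cohort>_with, <cohort>_without`` pairs."""
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty counts file")
        cohort_names = [
            f[: -len("_with")]
            for f in reader.fieldnames
            if f.endswith("_with") and f != "case_with"
        ]
        rows = []
        for rec in reader:
            rows.append(
                BurdenRow(
                    gene_symbol=rec["gene"],
                    case_with=int(rec["case_with"]),
                    case_without=int(rec["case_without"]),
                    cohort_counts={
                        name: (int(rec[f"{name}_with"]), int(rec[f"{name}_without"]))
                        for name in cohort_names
                    },
                )
            )
    return rows


def load_table1_counts() -> List[BurdenRow]:
    """The published per-gene carrier counts of the neuroblastoma germline
    burden analysis (52 patients, 104 for BARD1; three control cohorts),
    packaged as a fixture."""
    with resources.as_file(
        resources.files("nbexome.data").joinpath("table1_counts.tsv")
    ) as path:
        return read_burden_counts(path)
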