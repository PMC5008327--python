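"""Post-calling somatic filter cascade and the clinical subgroup classifier.

Raw tumor/normal variant calls are reduced to a high-confidence non-silent
somatic set by a fixed cascade of rules: sequencing depth in both tissues,
tumor alt-read support, tumor variant allele fraction (VAF), normal VAF
(germline contamination), dbSNP membership, and functional class.  Rejections
are audited against the FIRST rule a call fails, in that fixed order, so the
audit is reproducible and its counts sum to the number of rejected calls.

The exact thresholds used by the original study are not published; the
defaults below reflect common tumor/normal calling practice of the VarScan2
era and every one is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .types import NON_SILENT_CLASSES, VariantCall

#: Audit attribution order; a rejected call is charged to its first failure.
RULE_ORDER = ("depth", "alt_reads", "tumor_vaf", "normal_vaf", "dbsnp", "functional_class")


@dataclass(frozen=True)
class FilterConfig:
    min_tumor_depth: int = 14
    min_normal_depth: int = 8
    min_tumor_alt_reads: int = 4
    min_tumor_vaf: float = 0.10
    max_normal_vaf: float = 0.05
    exclude_dbsnp: bool = True
    retained_functional_classes: frozenset = field(default_factory=lambda: NON_SILENT_CLASSES)

    def validate(self) -> None:
        if self.min_tumor_depth < 1 or self.min_normal_depth < 1:
            raise ValueError("depth thresholds must be >= 1")
        if not (0 <= self.max_normal_vaf < self.min_tumor_vaf <= 1):
            raise ValueError(
                f"require 0 <= max_normal_vaf ({self.max_normal_vaf}) < "
                f"min_tumor_vaf ({self.min_tumor_vaf}) <= 1"
            )
        if self.min_tumor_alt_reads < 0:
            raise ValueError("min_tumor_alt_reads must be >= 0")
        if not self.retained_functional_classes:
            raise ValueError("retained_functional_classes is empty")


def _first_failed_rule(v: VariantCall, cfg: FilterConfig) -> Optional[str]:
    if v.tumor_depth < cfg.min_tumor_depth or v.normal_depth < cfg.min_normal_depth:
        return "depth"
    if v.tumor_alt_count < cfg.min_tumor_alt_reads:
        return "alt_reads"
    if v.tumor_vaf < cfg.min_tumor_vaf:
        return "tumor_vaf"
    if v.normal_vaf > cfg.max_normal_vaf:
        return "normal_vaf"
    if cfg.exclude_dbsnp and v.dbsnp_member:
        return "dbsnp"
    if v.functional_class not in cfg.retained_functional_classes:
        return "functional_class"
    return None


def filter_somatic_variants(
    calls: Iterable[VariantCall], config: FilterConfig = FilterConfig()
) -> Tuple[List[VariantCall], Dict[str, int]]:
    """Apply the filter cascade; return (retained calls, per-rule audit).

    The audit maps each rule name to the number of calls whose first failure
    was that rule; its values sum to ``len(calls) - len(retained)``.
    """
    config.validate()
    retained: List[VariantCall] = []
    audit: Dict[str, int] = {rule: 0 for rule in RULE_ORDER}
    for v in calls:
        rule = _first_failed_rule(v, config)
        if rule is None:
            retained.append(v)
        else:
            audit[rule] += 1
    return retained, audit


@dataclass(frozen=True)
class SampleMeta:
    """Clinical metadata of one patient sample."""

    sample_id: str
    risk_group: str  # low | intermediate | high
    adverse_event: bool = False
    months_to_event: Optional[float] = None

    def __post_init__(self) -> None:
        if self.risk_group not in ("low", "intermediate", "high"):
            raise ValueError(f"unknown risk_group {self.risk_group!r}")
        if self.adverse_event != (self.months_to_event is not None):
            raise ValueError("months_to_event must be present iff adverse_event")
        if self.months_to_event is not None and self.months_to_event < 0:
            raise ValueError("months_to_event must be non-negative")


def classify_subgroup(meta: SampleMeta) -> str:
    """Assign the clinical subgroup.

    ``hr_event3`` is the clinically aggressive subgroup: high-risk patients
    with any adverse event (progression, relapse or death) within 36 months
    of diagnosis, boundary inclusive.  Everyone else maps to their risk group.
    """
    if (
        meta.risk_group == "high"
        and meta.adverse_event
        and meta.months_to_event is not None
        and meta.months_to_event <= 36.0
    ):
        return "hr_event3"
    return f"{meta.risk_group}_risk"


def per_sample_summary(retained: Iterable[VariantCall]) -> Tuple[Dict[str, int], int]:
    """Per-sample non-silent mutation counts and their lower median.

    Returns ``(counts, median)`` where ``counts`` maps sample_id to its
    non-silent mutation count and ``median`` is the lower median across
    samples (the smaller of the two central order statistics when the number
    of samples is even).
    """
    counts: Dict[str, int] = {}
    for v in retained:
        if v.is_non_silent:
            counts[v.sample_id] = counts.get(v.sample_id, 0) + 1
    if not counts:
        raise ValueError("no non-silent variants; nothing to summarize")
    ordered = sorted(counts.values())
    median = ordered[(len(ordered) - 1) // 2]
    return counts, median
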