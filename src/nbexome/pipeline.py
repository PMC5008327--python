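"""End-to-end orchestration: filter -> spectrum -> signatures -> drivers ->
pathways -> germline burden, driven by a YAML-loadable configuration.

Every stage reads and writes files (no stage mutates its inputs), and a JSON
manifest records the package version, seed, SHA-256 digests of inputs and
outputs, and per-stage row counts, so an identical configuration and seed
reproduce identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import __version__
from .burden import burden_frame, burden_report, read_burden_counts
from .drivers import summaries_to_frame, summarize_genes
from .filtering import FilterConfig, filter_somatic_variants, per_sample_summary
from .gsea import gsea_preranked, rank_genes
from .io import (
    read_gmt,
    read_signature_matrix,
    read_variant_table,
    write_variant_table,
)
from .spectrum import CONTEXT_LABELS, build_spectrum, class_fractions, decompose

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    variants: str = "variants.maf.tsv"
    scores: str = "scores.tsv"
    gene_sets: Optional[str] = None
    signature_refs: Optional[str] = None
    burden_counts: Optional[str] = None
    out_dir: str = "results"
    n_samples: int = 17
    filter: FilterConfig = field(default_factory=FilterConfig)
    n_perm: int = 1000
    seed: int = 0
    weight_exponent: float = 1.0
    chasm_fdr_gate: float = 0.25
    vest_fdr_gate: float = 0.10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        filt = FilterConfig(**raw.pop("filter", {}))
        cfg = cls(filter=filt, **raw)
        if not (0 < cfg.chasm_fdr_gate < 1 and 0 < cfg.vest_fdr_gate < 1):
            raise ValueError("FDR gates must be in (0, 1)")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run all stages in order, returning the manifest (also written to
    ``<out_dir>/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "package": "nbexome",
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "stages": {},
        "outputs": {},
    }
    for name in ("variants", "scores", "gene_sets", "signature_refs", "burden_counts"):
        path = getattr(config, name)
        if path is not None:
            p = Path(path)
            if not p.exists():
                raise PipelineError(name, f"input file {path} does not exist")
            manifest["inputs"][name] = _sha256(p)

    # filter
    try:
        calls = read_variant_table(config.variants)
        retained, audit = filter_somatic_variants(calls, config.filter)
        write_variant_table(retained, out / "filtered.maf.tsv")
        counts, median = per_sample_summary(retained) if retained else ({}, 0)
        manifest["stages"]["filter"] = {
            "n_input": len(calls),
            "n_retained": len(retained),
            "audit": audit,
            "median_nonsilent_per_sample": median,
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc

    # spectrum
    try:
        spectrum = build_spectrum(retained)
        pd.DataFrame({"context": CONTEXT_LABELS, "count": spectrum.counts}).to_csv(
            out / "spectrum.tsv", sep="\t", index=False
        )
        fractions = class_fractions(spectrum) if spectrum.total else {}
        manifest["stages"]["spectrum"] = {
            "total_snvs": spectrum.total,
            "class_fractions": {k: float(v) for k, v in fractions.items()},
        }
    except Exception as exc:
        raise PipelineError("spectrum", str(exc)) from exc

    # signatures
    if config.signature_refs is not None:
        try:
            refs = read_signature_matrix(config.signature_refs)
            exposure = decompose(spectrum, refs)
            pd.DataFrame(
                {"signature": list(exposure.weights), "weight": list(exposure.weights.values())}
            ).to_csv(out / "exposures.tsv", sep="\t", index=False)
            manifest["stages"]["signatures"] = {
                "weights": {k: float(v) for k, v in exposure.weights.items()},
                "residual_norm": exposure.residual_norm,
            }
        except Exception as exc:
            raise PipelineError("signatures", str(exc)) from exc

    # drivers
    try:
        if not Path(config.scores).exists():
            raise FileNotFoundError(f"scores file {config.scores} does not exist")
        scores = pd.read_csv(config.scores, sep="\t")
        summaries = summarize_genes(
            retained,
            scores,
            config.n_samples,
            chasm_fdr_gate=config.chasm_fdr_gate,
            vest_fdr_gate=config.vest_fdr_gate,
        )
        summaries_to_frame(summaries).to_csv(out / "drivers.tsv", sep="\t", index=False)
        manifest["stages"]["drivers"] = {
            "n_genes": len(summaries),
            "n_significant": sum(s.significant for s in summaries),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("drivers", str(exc)) from exc

    # pathways
    if config.gene_sets is not None:
        try:
            sets = read_gmt(config.gene_sets)
            ranked = rank_genes(summaries)
            usable = [s for s in sets if s.genes & set(ranked.genes)]
            results = gsea_preranked(
                ranked, usable, n_perm=config.n_perm, seed=config.seed,
                weight_exponent=config.weight_exponent,
            )
            pd.DataFrame(
                {
                    "set_name": [r.set_name for r in results],
                    "es": [r.es for r in results],
                    "nes": [r.nes for r in results],
                    "p_perm": [r.p_perm for r in results],
                    "fdr": [r.fdr for r in results],
                    "leading_edge": [",".join(sorted(r.leading_edge)) for r in results],
                }
            ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["pathways"] = {
                "n_sets": len(results),
                "n_fdr_le_0.05": sum(r.fdr <= 0.05 for r in results),
            }
        except Exception as exc:
            raise PipelineError("pathways", str(exc)) from exc

    # germline burden
    if config.burden_counts is not None:
        try:
            rows = burden_report(read_burden_counts(config.burden_counts))
            burden_frame(rows).to_csv(out / "burden.tsv", sep="\t", index=False)
            manifest["stages"]["germline_burden"] = {
                "n_genes": len(rows),
                "top_gene": rows[0].gene_symbol,
            }
        except Exception as exc:
            raise PipelineError("germline_burden", str(exc)) from exc

    for artifact in sorted(out.glob("*.tsv")):
        manifest["outputs"][artifact.name] = _sha256(artifact)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
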