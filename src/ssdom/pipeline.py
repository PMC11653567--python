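"""Configuration-driven orchestration of the per-cross workflow.

Each cross runs independently through: Y-linked removal -> low-count
filter -> size factors -> variance-stabilizing transform -> mis-sexed
sample detection and exclusion -> two-step focal filter -> dominance
stage -> summary statistics -> optional GO over-representation.  The run
report records every removal / retention count in order, and re-running
with the same inputs is bit-identical (nothing downstream of the input
data is stochastic).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io, preprocess, posthoc, enrichment
from .data_io import CountMatrix
from .dominance import analyze_cross
from .errors import ConfigError

log = logging.getLogger("ssdom")


@dataclass
class RunConfig:
    """Paths and thresholds for a pipeline run."""

    counts_path: str = ""
    samples_path: str = ""
    genes_path: str = ""
    go_map_path: str | None = None
    out_dir: str = "results"
    q_cutoff: float = 0.05
    low_count_threshold: float = 3.0
    low_count_scope: str = "all_sexes"
    go_min_term_size: int = 5
    detect_mis_sexed: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.q_cutoff <= 0 or self.q_cutoff >= 1:
            raise ConfigError("q_cutoff must be in (0, 1)")
        if self.low_count_threshold < 0:
            raise ConfigError("low_count_threshold must be >= 0")
        if self.go_min_term_size < 1:
            raise ConfigError("go_min_term_size must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineResult:
    results: pd.DataFrame
    report: dict
    summaries: dict
    enrichments: dict = field(default_factory=dict)


def run_from_memory(counts: CountMatrix, samples: pd.DataFrame,
                    genes: pd.DataFrame, go_map: pd.DataFrame | None = None,
                    q_cutoff: float = 0.05, low_count_threshold: float = 3.0,
                    low_count_scope: str = "all_sexes",
                    detect_mis_sexed: bool = True,
                    go_min_term_size: int = 5) -> PipelineResult:
    """Run every analysis stage on in-memory inputs, cross by cross."""
    data_io.validate_design(samples)
    all_results = []
    report: dict = {"crosses": {}}
    summaries: dict = {}
    enrichments: dict = {}
    for cross_id in pd.unique(samples["cross"]):
        sub = samples[samples["cross"] == cross_id].reset_index(drop=True)
        cm = counts.subset_samples(list(sub["sample_id"]))
        n0 = cm.n_genes
        crep: dict = {"n_transcripts_input": int(n0), "n_samples_input": int(len(sub))}

        cm = preprocess.filter_y_linked(cm, genes)
        crep["y_linked_removed"] = int(n0 - cm.n_genes)
        n1 = cm.n_genes
        cm = preprocess.filter_low_expression(cm, sub, low_count_threshold,
                                              low_count_scope)
        crep["low_count_removed"] = int(n1 - cm.n_genes)
        crep["n_transcripts_retained"] = int(cm.n_genes)

        sf = preprocess.size_factors_design_aware(cm, sub)
        flagged: list[str] = []
        if detect_mis_sexed:
            nm = preprocess.vst(cm, sf)
            flagged = preprocess.detect_mis_sexed(nm, sub)
            sub = preprocess.mark_excluded(sub, flagged, "mis-sexed (PC outlier)")
        crep["samples_flagged"] = list(flagged)
        crep["n_samples_removed"] = len(flagged)

        kept = sub[~sub["excluded"]].reset_index(drop=True)
        crep["n_samples_retained"] = int(len(kept))
        cm = cm.subset_samples(list(kept["sample_id"]))
        sf = preprocess.size_factors_design_aware(cm, kept)

        analysis = analyze_cross(cm, kept, genes, sf, q_cutoff=q_cutoff)
        crep.update({k: v for k, v in analysis.report.items() if k != "cross"})
        all_results.append(analysis.results)
        summaries[str(cross_id)] = posthoc.summarize_cross(analysis.results, q_cutoff)

        if go_map is not None:
            aut = analysis.results[(analysis.results["chrom_class"] == "autosome")
                                   & analysis.results["focal"]]
            universe = list(aut["gene_id"])
            study = list(aut.loc[aut["ssd"], "gene_id"])
            covered = go_map["gene_id"].isin(universe).any()
            if study and covered:
                enrichments[str(cross_id)] = enrichment.go_overrepresentation(
                    study, universe, go_map, min_size=go_min_term_size)
        report["crosses"][str(cross_id)] = crep

    results = pd.concat(all_results, ignore_index=True)
    report["total_ssd"] = int(results.loc[results["chrom_class"] == "autosome",
                                          "ssd"].sum())
    return PipelineResult(results=results, report=report, summaries=summaries,
                          enrichments=enrichments)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load inputs per the config, run everything, write outputs.

    Writes, under `out_dir`: results_<cross>.tsv per cross, a combined
    results.tsv, summary.json (post-hoc statistics), report.json (the
    per-stage counts), and enrichment_<cross>.tsv when a GO map is given.
    """
    config.validate()
    counts = data_io.read_counts(config.counts_path)
    samples = data_io.read_samples(config.samples_path, counts)
    genes = data_io.read_genes(config.genes_path, counts)
    go_map = (data_io.read_go_map(config.go_map_path)
              if config.go_map_path else None)

    out = run_from_memory(
        counts, samples, genes, go_map=go_map, q_cutoff=config.q_cutoff,
        low_count_threshold=config.low_count_threshold,
        low_count_scope=config.low_count_scope,
        detect_mis_sexed=config.detect_mis_sexed,
        go_min_term_size=config.go_min_term_size,
    )

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_io.write_results(out.results, out_dir / "results.tsv")
    for cross_id, sub in out.results.groupby("cross_id"):
        data_io.write_results(sub, out_dir / f"results_{cross_id}.tsv")
    for cross_id, enr in out.enrichments.items():
        enr.to_csv(out_dir / f"enrichment_{cross_id}.tsv", sep="\t", index=False)
    (out_dir / "summary.json").write_text(
        json.dumps(_jsonable(out.summaries), indent=2))
    (out_dir / "report.json").write_text(
        json.dumps(_jsonable({**out.report, "config": asdict(config)}), indent=2))
    log.info("pipeline finished; outputs in %s", out_dir)
    return out
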