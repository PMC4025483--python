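"""End-to-end pipeline runs: file in, report bundle out.

Ties the stages together the way the full analysis is run: read an
expression table and an annotation catalog, decompose, rank genes per
pattern, test enrichment, and write the artifacts (eigengene table,
spectrum summary, ranked lists, enrichment report, run log); similarly
for the metabolome and store branches.  Configuration comes from a YAML
file with flag overrides layered on top by the CLI.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .eigengenes import cumulative_fraction, decompose, rank_genes
from .enrichment import enrich, read_catalog
from .expression import read_expression
from .metabolomics import (
    analyze_stores,
    normalize_to_standard,
    ratio_series,
    read_stores,
    read_timecourse,
    relative_to_baseline,
    summarize,
)

__all__ = ["PipelineConfig", "run_eigengene_pipeline", "run_metabolome_pipeline", "run_store_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration; any field may come from YAML or CLI flags."""

    expression_path: str | None = None
    catalog_path: str | None = None
    metabolite_path: str | None = None
    stores_path: str | None = None
    output_dir: str = "eigenmet_out"
    baseline: str = "0-2h"
    top_n: int = 500
    patterns: list[int] = field(default_factory=lambda: [1, 2, 3])
    alpha_metabolites: float = 0.01
    alpha_stores: float = 0.05
    transform: str = "none"
    center: bool = False
    ratio_pairs: list[list[str]] = field(default_factory=list)
    make_figures: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for a in (self.alpha_metabolites, self.alpha_stores):
            if not 0 < a < 1:
                raise ValueError(f"alpha {a} not in (0, 1)")
        for p in (self.expression_path, self.catalog_path, self.metabolite_path, self.stores_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _write_run_log(outdir: Path, config: PipelineConfig, extra: dict) -> None:
    log = {
        "eigenmet_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": asdict(config),
        **extra,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))


def run_eigengene_pipeline(config: PipelineConfig) -> dict:
    """Decompose an expression table, rank genes, test enrichment.

    Writes into ``config.output_dir``: ``eigengenes.tsv`` (patterns ×
    timepoints), ``spectrum.json`` (singular values, fractions, entropy,
    top-3 cumulative fraction), one ``ranked_pattern<i>.tsv`` per
    requested pattern, ``enrichment.tsv``/``.json`` when a catalog is
    given, and ``run_log.json``.  Returns the bundle as a dict.
    """
    config.validate()
    if config.expression_path is None:
        raise ValueError("expression_path is required")
    matrix = read_expression(config.expression_path)
    if config.top_n > matrix.n_genes:
        raise ValueError(
            f"top_n={config.top_n} exceeds gene count {matrix.n_genes}"
        )
    decomp = decompose(matrix, transform=config.transform, center=config.center)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    eig = pd.DataFrame(
        decomp.eigengenes,
        index=[f"pattern{i + 1}" for i in range(decomp.n_patterns)],
        columns=decomp.stage_labels,
    )
    eig.to_csv(outdir / "eigengenes.tsv", sep="\t", index_label="pattern")

    spectrum = {
        "n_patterns": decomp.n_patterns,
        "singular_values": decomp.singular_values.tolist(),
        "fractions": decomp.fractions.tolist(),
        "entropy": decomp.entropy,
        "top3_cumulative_fraction": cumulative_fraction(
            decomp.fractions, min(3, decomp.n_patterns)
        ),
    }
    (outdir / "spectrum.json").write_text(json.dumps(spectrum, indent=2))

    ranked = {}
    for pi in config.patterns:
        rl = rank_genes(decomp, pi, top_n=config.top_n)
        ranked[pi] = rl
        pd.DataFrame(rl.entries, columns=["gene_id", "loading"]).to_csv(
            outdir / f"ranked_pattern{pi}.tsv", sep="\t", index=False
        )

    enrichment = {}
    if config.catalog_path is not None:
        catalog = read_catalog(config.catalog_path, universe=matrix.gene_ids)
        records = []
        for pi, rl in ranked.items():
            res = enrich(rl, catalog)
            enrichment[pi] = res
            records.append({"pattern": pi, **res.as_dict()})
        table = pd.DataFrame(records)
        table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        (outdir / "enrichment.json").write_text(
            json.dumps(records, indent=2, default=float)
        )

    if config.make_figures:
        from .plotting import plot_eigengenes

        plot_eigengenes(decomp, outdir / "eigengenes.png")

    _write_run_log(outdir, config, {"stage": "eigengene", "n_genes": matrix.n_genes})
    return {
        "decomposition": decomp,
        "spectrum": spectrum,
        "ranked": ranked,
        "enrichment": enrichment,
    }


def run_metabolome_pipeline(config: PipelineConfig) -> dict:
    """Normalize, rescale to baseline, summarize and test a peak table.

    Writes ``metabolite_summary.tsv`` (one row per metabolite × bin),
    ``significant_changes.json``, optional ratio-series TSVs and box-plot
    figures, and ``run_log.json``.
    """
    config.validate()
    if config.metabolite_path is None:
        raise ValueError("metabolite_path is required")
    tc = read_timecourse(config.metabolite_path)
    if config.baseline not in tc.timepoint_order:
        raise ValueError(
            f"baseline {config.baseline!r} not among timepoints {tc.timepoint_order}"
        )
    normed = normalize_to_standard(tc)
    scaled = relative_to_baseline(normed, baseline=config.baseline)
    summary = summarize(scaled, baseline=config.baseline, alpha=config.alpha_metabolites)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(outdir / "metabolite_summary.tsv", sep="\t", index=False)

    sig = summary[summary["significant"]]
    (outdir / "significant_changes.json").write_text(
        json.dumps(
            sig[["metabolite", "timepoint", "median", "p_value"]].to_dict("records"),
            indent=2,
        )
    )

    ratios = {}
    for pair in config.ratio_pairs:
        num, den = pair
        series = ratio_series(scaled, num, den)
        series.to_csv(outdir / f"ratio_{num}_over_{den}.tsv", sep="\t", index=False)
        ratios[f"{num}/{den}"] = series

    if config.make_figures:
        from .plotting import plot_metabolite_boxes

        plot_metabolite_boxes(scaled, outdir / "metabolites.png")

    _write_run_log(
        outdir, config, {"stage": "metabolome", "n_metabolites": len(tc.metabolite_names)}
    )
    return {"timecourse": scaled, "summary": summary, "ratios": ratios}


def run_store_pipeline(config: PipelineConfig) -> dict:
    """Baseline-relative store statistics for every analyte in the table."""
    config.validate()
    if config.stores_path is None:
        raise ValueError("stores_path is required")
    assays = read_stores(config.stores_path)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = [analyze_stores(a, alpha=config.alpha_stores) for a in assays]
    result = pd.concat(tables, ignore_index=True)
    result.to_csv(outdir / "store_summary.tsv", sep="\t", index=False)
    _write_run_log(outdir, config, {"stage": "stores", "n_analytes": len(assays)})
    return {"summary": result}
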