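"""End-to-end pipeline: simulate (or read) -> QC -> normalize -> DE -> patterning.

Every stage writes its outputs before the next stage begins, and every
source of randomness flows from the single configuration seed, so a run is
byte-reproducible: identical config + inputs + seed give byte-identical
CSV outputs.  A manifest (config snapshot, version, per-stage row counts,
warnings) accompanies every run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

import stresspattern
from stresspattern import io as spio
from stresspattern.containers import InputError
from stresspattern.de import run_all_comparisons
from stresspattern.patterning import build_pattern_profiles, cluster_patterning_summary, split_by_score
from stresspattern.qc import QCThresholds, eligible_clusters, normalize_log, qc_filter
from stresspattern.simulate import SimDesign, default_patterns, generate_counts

log = logging.getLogger("stresspattern")

FLOAT_FORMAT = "%.10g"  # fixed float rendering => byte-stable CSV output


@dataclass
class PipelineConfig:
    """Full pipeline configuration with the study's default thresholds."""

    input_dir: str | None = None  # read counts from here; None => simulate
    # simulation block
    n_clusters: int = 3
    cells_per_cluster_per_sample: tuple = (120, 60, 20)
    n_genes: int = 2000
    n_groups: int = 3
    effect_size: float = 1.5
    genes_per_pattern: int = 4
    # QC block
    min_counts: int = 1000
    max_counts: int = 30000
    min_genes: int = 500
    max_mito_fraction: float = 0.2
    min_cells_per_gene: int = 10
    # DE block
    q_max: float = 0.05
    min_mean: float = 0.5
    min_abs_l2fc: float = 0.5
    min_cluster_cells: int = 300
    # patterning block
    top_n: int = 30
    combine: str = "mean"
    # behaviour block
    retreat_sign: float = 1.0
    # run block
    outdir: str = "stresspattern_out"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cells_per_cluster_per_sample"] = list(self.cells_per_cluster_per_sample) \
            if not isinstance(self.cells_per_cluster_per_sample, int) \
            else self.cells_per_cluster_per_sample
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise InputError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**d)
        if isinstance(cfg.cells_per_cluster_per_sample, list):
            cfg.cells_per_cluster_per_sample = tuple(cfg.cells_per_cluster_per_sample)
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stage_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    status: str = "running"

    def write(self, outdir: str) -> None:
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _write_csv(df, path: str, index: bool = False, **kw) -> None:
    df.to_csv(path, float_format=FLOAT_FORMAT, index=index, **kw)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline, writing each stage's outputs as it goes."""
    os.makedirs(config.outdir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest = RunManifest(config=config.to_dict(),
                           version=stresspattern.__version__,
                           seed=config.seed)
    caught: list[str] = []
    try:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")

            # --- input stage: simulate or read --------------------------------
            if config.input_dir is None:
                design = SimDesign(
                    n_clusters=config.n_clusters,
                    cells_per_cluster_per_sample=config.cells_per_cluster_per_sample,
                    n_genes=config.n_genes,
                    n_groups=config.n_groups,
                    seed=config.seed,
                )
                patterns = default_patterns(design,
                                            n_per_type=config.genes_per_pattern,
                                            effect_size=config.effect_size)
                matrix, truth = generate_counts(design, patterns)
                counts_dir = os.path.join(config.outdir, "counts")
                spio.write_count_matrix(matrix, counts_dir)
                _write_csv(truth.genes, os.path.join(config.outdir, "truth_genes.csv"))
                _write_csv(truth.batch_effects,
                           os.path.join(config.outdir, "truth_batches.csv"))
                log.info("simulated %d genes x %d cells", matrix.n_genes, matrix.n_cells)
            else:
                matrix = spio.read_count_matrix(config.input_dir)
                log.info("read %d genes x %d cells from %s",
                         matrix.n_genes, matrix.n_cells, config.input_dir)
            manifest.stage_counts["input_cells"] = matrix.n_cells
            manifest.stage_counts["input_genes"] = matrix.n_genes

            # --- QC -----------------------------------------------------------
            thresholds = QCThresholds(
                min_counts=config.min_counts, max_counts=config.max_counts,
                min_genes=config.min_genes,
                max_mito_fraction=config.max_mito_fraction,
                min_cells_per_gene=config.min_cells_per_gene)
            filtered, report = qc_filter(matrix, thresholds)
            import pandas as pd
            _write_csv(pd.DataFrame([report.as_dict()]),
                       os.path.join(config.outdir, "qc_report.csv"))
            manifest.stage_counts["qc_cells"] = filtered.n_cells
            manifest.stage_counts["qc_genes"] = filtered.n_genes

            # --- normalize ----------------------------------------------------
            norm = normalize_log(filtered, method="library_size")
            _write_csv(pd.DataFrame({"barcode": norm.cells.index,
                                     "size_factor": norm.size_factors}),
                       os.path.join(config.outdir, "size_factors.csv"))

            # --- cluster eligibility -----------------------------------------
            eligible = eligible_clusters(norm, min_total_cells=config.min_cluster_cells)
            all_counts = norm.cells["cluster"].value_counts().sort_index()
            _write_csv(pd.DataFrame({"cluster": all_counts.index,
                                     "n_cells": all_counts.to_numpy(),
                                     "eligible": [c in eligible
                                                  for c in all_counts.index]}),
                       os.path.join(config.outdir, "clusters.csv"))
            manifest.stage_counts["eligible_clusters"] = len(eligible)

            # --- differential expression -------------------------------------
            results, degsets, count_table = run_all_comparisons(
                norm, eligible, q_max=config.q_max, min_mean=config.min_mean,
                min_abs_l2fc=config.min_abs_l2fc)
            _write_csv(results, os.path.join(config.outdir, "de_results.csv"))
            _write_csv(count_table, os.path.join(config.outdir, "deg_counts.csv"))
            deg_dir = os.path.join(config.outdir, "degs")
            os.makedirs(deg_dir, exist_ok=True)
            for (cluster, comp), ds in sorted(degsets.items()):
                with open(os.path.join(deg_dir, f"{cluster}_{comp}.txt"), "w") as fh:
                    for g in ds.up:
                        fh.write(f"{g}\tup\n")
                    for g in ds.down:
                        fh.write(f"{g}\tdown\n")
            manifest.stage_counts["de_tests"] = len(results)
            manifest.stage_counts["degs_total"] = int(count_table["n_degs"].sum()) \
                if not count_table.empty else 0

            # --- patterning ---------------------------------------------------
            profiles = build_pattern_profiles(results, degsets, expr=norm,
                                              combine=config.combine)
            _write_csv(profiles, os.path.join(config.outdir, "pattern_profiles.csv"))
            manifest.stage_counts["patterned_genes"] = len(profiles)
            if not profiles.empty:
                summary = cluster_patterning_summary(profiles)
                _write_csv(summary, os.path.join(config.outdir, "pattern_summary.csv"))
                tier_dir = os.path.join(config.outdir, "tiers")
                os.makedirs(tier_dir, exist_ok=True)
                for cluster, grp in profiles.groupby("cluster"):
                    if len(grp) < 4:
                        continue
                    top, mid, low = split_by_score(grp)
                    for name, genes in (("top25", top), ("mid50", mid),
                                        ("low25", low)):
                        with open(os.path.join(tier_dir,
                                               f"{cluster}_{name}.txt"), "w") as fh:
                            fh.write("\n".join(genes) + ("\n" if genes else ""))

            manifest.warnings = sorted({str(w.message) for w in wrec})
        manifest.status = "ok"
    except Exception as exc:
        manifest.status = f"failed: {exc}"
        manifest.write(config.outdir)
        raise
    manifest.write(config.outdir)
    return manifest
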