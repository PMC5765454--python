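"""Experiment orchestration: sweep cells, seeding, outputs.

An experiment is a grid of cells — combinations of selection strength S,
dispersal probability d, and mating-system mode — each run for a number of
replicates.  Every (cell, replicate) gets an independent random stream
derived from the master seed by a counter scheme:
``SeedSequence([master_seed, cell_index, replicate_index])``; the seeds are
recorded in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import lifecycle, observers
from .config import ModelConfig

S_SWEEP = (0.0, 0.002, 0.006, 0.01, 0.02, 0.03, 0.04)
D_SWEEP = (0.1, 0.01, 0.001)


def experiment_cells(S_values=S_SWEEP, d_values=D_SWEEP,
                     modes=("evolving_polyandry",)) -> list[dict]:
    """Cross the sweep axes into a list of config-override dicts."""
    cells = []
    for m in modes:
        for S in S_values:
            for d in d_values:
                cells.append({"selection_coefficient": float(S),
                              "dispersal_probability": float(d),
                              "mode": m})
    return cells


def replicate_rng(master_seed: int, cell_index: int,
                  replicate: int) -> np.random.Generator:
    """Independent stream for one (cell, replicate) pair."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, cell_index, replicate]))


def cell_label(cell: dict) -> str:
    S = cell.get("selection_coefficient")
    d = cell.get("dispersal_probability")
    mode = cell.get("mode", "evolving_polyandry")
    return f"S{S:g}_d{d:g}_{mode}"


def run_cell(config: ModelConfig, cell: dict, cell_index: int,
             replicates: int | None = None) -> list[observers.ReplicateResult]:
    """Run all replicates of one cell, returning their results."""
    cfg = config.replace(**cell)
    reps = replicates if replicates is not None else cfg.replicates
    results = []
    for j in range(reps):
        rng = replicate_rng(cfg.master_seed, cell_index, j)
        results.append(lifecycle.run_replicate(cfg, rng))
    return results


def run_experiment(config: ModelConfig, outdir, cells: list[dict] | None = None,
                   write_series: bool = True) -> pd.DataFrame:
    """Run every cell x replicate, write outputs, return the summary table.

    Outputs under ``outdir``: per-replicate GenerationRecord time series
    (TSV, config echoed in the header), ``summary.tsv`` with one row per
    (cell, replicate), per-cell across-replicate mean +/- SD tables, and a
    ``manifest.json`` recording the config, seeds, versions and wall-clock.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cells is None:
        cells = [{"selection_coefficient": config.selection_coefficient,
                  "dispersal_probability": config.dispersal_probability,
                  "mode": config.mode}]
    t0 = time.time()
    summary_rows = []
    manifest_cells = []
    for i, cell in enumerate(cells):
        cfg = config.replace(**cell)
        label = cell_label(cell)
        cell_dir = outdir / label
        cell_dir.mkdir(exist_ok=True)
        seeds = []
        cell_summaries = []
        for j in range(cfg.replicates):
            rng = replicate_rng(cfg.master_seed, i, j)
            seeds.append([cfg.master_seed, i, j])
            result = lifecycle.run_replicate(cfg, rng)
            if write_series:
                observers.write_records(cell_dir / f"rep{j:03d}.tsv",
                                        result, cfg)
            s = result.summary()
            s.update(cell=label, replicate=j, **cell)
            cell_summaries.append(s)
            summary_rows.append(s)
        observers.summarize_replicates(cell_summaries).to_csv(
            cell_dir / "across_replicates.tsv", sep="\t")
        manifest_cells.append({"index": i, "label": label,
                               "overrides": cell, "seeds": seeds})
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    cfg_yaml = config.to_yaml()
    manifest = {
        "software": "polyandrysim",
        "version": __version__,
        "config": cfg_yaml,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "cells": manifest_cells,
        "wall_clock_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary


def summarize(summary_path, out_path=None) -> pd.DataFrame:
    """Aggregate a summary.tsv into per-cell across-replicate mean +/- SD."""
    df = pd.read_csv(summary_path, sep="\t")
    num_cols = df.select_dtypes(include=[np.number]).columns
    num_cols = [c for c in num_cols if c != "replicate"]
    agg = df.groupby("cell")[num_cols].agg(["mean", "std"])
    if out_path is not None:
        agg.to_csv(out_path, sep="\t")
    return agg
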