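"""End-to-end orchestration: preprocess -> CNV -> K selection -> HASC.

Every stage writes its TSV artifacts into the output directory and the run
finishes with a JSON manifest (package version, parameters, seed, SHA-256 of
the inputs and headline results) sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cnv import cnv_burden, infer_cnv, order_genes
from .hasc import hasc_test, proportion_table
from .io import read_10x, read_bulk, read_cell_meta, read_positions
from .kselect import select_k
from .preprocess import filter_counts, lognormalize
from .ssgsea import write_gmt

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("cnvselect")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    mtx_dir: str
    meta: str
    positions: str
    bulk: str
    outdir: str
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    scale_factor: float = 1e4
    cutoff: float = 0.1
    window: int = 101
    clamp: float = 3.0
    k_min: int = 6
    k_max: int = 15
    n_init: int = 10
    n_top_genes: int = 50
    ssgsea_alpha: float = 0.25
    hasc_alpha: float = 0.05
    correction: str = "bonferroni"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("mtx_dir", "meta", "positions", "bulk"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"{name}: {getattr(self, name)} does not exist")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError(f"bad K range [{self.k_min}, {self.k_max}]")
        if self.window % 2 == 0 or self.window < 1:
            raise ValueError("window must be a positive odd integer")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _input_hashes(config: RunConfig) -> dict[str, str]:
    hashes = {}
    mtx_dir = Path(config.mtx_dir)
    for p in sorted(mtx_dir.iterdir()):
        if p.is_file():
            hashes[f"mtx/{p.name}"] = _sha256(p)
    for name in ("meta", "positions", "bulk"):
        hashes[name] = _sha256(Path(getattr(config, name)))
    return hashes


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "cnvselect",
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "inputs": _input_hashes(config),
        "stages": {},
    }

    def stage(name):
        log.info("[%s] starting", name)

    try:
        stage("load")
        adata = read_10x(config.mtx_dir)
        read_cell_meta(config.meta, adata)
        positions = read_positions(config.positions)
        cohort = read_bulk(config.bulk)
    except Exception as err:  # noqa: BLE001
        raise PipelineError("load", err) from err

    try:
        stage("preprocess")
        filtered = filter_counts(
            adata, config.min_cells_per_gene, config.min_genes_per_cell
        )
        normalized = lognormalize(filtered, config.scale_factor)
        manifest["stages"]["preprocess"] = {
            "n_cells_in": int(adata.n_obs),
            "n_genes_in": int(adata.n_vars),
            "n_cells_kept": int(normalized.n_obs),
            "n_genes_kept": int(normalized.n_vars),
        }
    except Exception as err:  # noqa: BLE001
        raise PipelineError("preprocess", err) from err

    try:
        stage("cnv")
        ordered = order_genes(normalized, positions)
        profile = infer_cnv(
            ordered, cutoff=config.cutoff, window=config.window, clamp=config.clamp
        )
        profile.chrom_features.to_csv(outdir / "chrom_features.tsv", sep="\t")
        cnv_burden(profile).to_csv(outdir / "cnv_burden.tsv", sep="\t")
        manifest["stages"]["cnv"] = {
            "n_genes_profiled": len(profile.gene_order),
            "n_chromosomes": int(profile.chrom_features.shape[1]),
            "params": profile.params,
        }
    except Exception as err:  # noqa: BLE001
        raise PipelineError("cnv", err) from err

    try:
        stage("kselect")
        result = select_k(
            ordered,
            profile.chrom_features.to_numpy(),
            cohort,
            k_min=config.k_min,
            k_max=config.k_max,
            seed=config.seed,
            n_init=config.n_init,
            n_top_genes=config.n_top_genes,
            alpha=config.ssgsea_alpha,
        )
        summary = result.summary()
        summary.to_csv(outdir / "kselect_report.tsv", sep="\t", index=False)
        sel = result.selected
        assignment = pd.DataFrame(
            {
                "cell_id": np.asarray(ordered.obs_names),
                "cluster": sel.labels,
                "is_malignant": result.malignant_mask(),
            }
        )
        assignment.to_csv(outdir / "cell_assignment.tsv", sep="\t", index=False)
        sets = [r.gene_set for r in result.per_k.values() if r.gene_set is not None]
        if sets:
            write_gmt(
                [dataclasses.replace(s, name=f"K{k}_{s.name}")
                 for k, s in ((r.k, r.gene_set) for r in result.per_k.values()
                              if r.gene_set is not None)],
                outdir / "gene_sets.gmt",
            )
        manifest["stages"]["kselect"] = {
            "selected_k": int(result.selected_k),
            "per_k": [
                {"K": int(row.K), "p_value": float(row.p_value),
                 "n_malignant_cells": int(row.n_malignant_cells),
                 "degenerate": bool(row.degenerate)}
                for row in summary.itertuples()
            ],
        }
    except Exception as err:  # noqa: BLE001
        raise PipelineError("kselect", err) from err

    try:
        stage("hasc")
        if "cell_type" in ordered.obs and "is_HT" in ordered.obs:
            table = proportion_table(
                ordered.obs["cell_type"].to_numpy(), ordered.obs["is_HT"].to_numpy()
            )
            ht = hasc_test(table, alpha=config.hasc_alpha, correction=config.correction)
            ht.table.to_csv(outdir / "hasc.tsv", sep="\t")
            manifest["stages"]["hasc"] = {
                "global_chi2": ht.global_chi2,
                "global_p": ht.global_p,
                "correction": ht.correction,
                "hascs": ht.hascs,
            }
        else:
            manifest["stages"]["hasc"] = {"skipped": "no cell_type / is_HT metadata"}
    except Exception as err:  # noqa: BLE001
        raise PipelineError("hasc", err) from err

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
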