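"""End-to-end orchestration: simulate -> filter -> reference -> train ->
classify -> evaluate, plus the expression QC / ligand-receptor branch.

A run is described by a :class:`RunConfig` (YAML/JSON serialisable, every
threshold defaulting to the published value where one exists). Each stage
writes its outputs before the next starts; a :class:`RunManifest` records
per-stage output digests, wall-clock and the seed fan-out, so a run is
auditable and any single stage re-executable. One top-level seed fans out to
per-stage seeds through a stable SeedSequence derivation keyed on the stage
name (see ``matfet._dist.spawn_seed``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from ._dist import spawn_seed
from .features import compute_difference_ratios
from .filters import filter_records
from .origin import CellOriginModel, evaluate_calls
from .reference import panels_from_cord_cells
from .simulate import (
    simulate_cell_allele_counts,
    simulate_expression_matrix,
    simulate_trio_genotypes,
    simulate_variant_records,
)

log = logging.getLogger("matfet.pipeline")


class ConfigError(ValueError):
    """Aggregated configuration violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


@dataclass
class RunConfig:
    """All knobs of one pipeline run, with published defaults.

    ``sections`` mirrors the three tissue slices of the sampling design
    (fetal side, middle, maternal side); each section is processed
    individually with its own model and thresholds.
    """

    seed: int = 0
    out_dir: str = "matfet_run"
    simulate: bool = True
    sections: tuple = ("FS", "Mid_S", "Mat_S")

    # trio / cells
    n_sites: int = 5000
    informative_fraction: float = 0.3
    n_cells: int = 600
    fetal_fraction: float = 0.5
    error_rate: float = 0.01
    mean_sites_per_cell: float = 30.0
    sites_dispersion: float = 30.0

    # cord reference panels
    n_panels: int = 3
    cord_cells_per_panel: int = 300
    cord_mean_sites: float = 150.0
    panel_min_support: int = 3

    # origin inference
    train_fraction: float = 0.5
    min_sites: int = 10
    ridge: Optional[float] = None
    cap: float = 1e6
    criterion: str = "accuracy"
    difference_mode: str = "alt_support"
    feature_space: str = "panel"  # or "chrom"

    # variant filtering
    filter_profile: str = "cell_snv"
    n_variant_records: int = 500

    # expression branch
    run_expression: bool = True
    n_genes: int = 2000
    n_expr_cells: int = 500
    min_cell_fraction: float = 0.001
    min_genes: int = 800
    max_mito: float = 0.10
    lr_min_prevalence: float = 0.40

    # external inputs when simulate=False
    trio_vcf: Optional[str] = None
    observations_tsv: Optional[str] = None
    labels_tsv: Optional[str] = None

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError([f"unknown config key: {k}" for k in sorted(unknown)])
        if "sections" in data:
            data = {**data, "sections": tuple(data["sections"])}
        return cls(**data)


def validate_config(config: RunConfig) -> list[str]:
    """Range-check every fraction, count and path; return all violations."""
    v: list[str] = []
    fr = {
        "informative_fraction": config.informative_fraction,
        "fetal_fraction": config.fetal_fraction,
        "train_fraction": config.train_fraction,
        "min_cell_fraction": config.min_cell_fraction,
        "max_mito": config.max_mito,
        "lr_min_prevalence": config.lr_min_prevalence,
    }
    for name, val in fr.items():
        if not 0.0 <= val <= 1.0:
            v.append(f"{name} must be in [0, 1], got {val}")
    if not 0.0 <= config.error_rate < 1.0:
        v.append(f"error_rate must be in [0, 1), got {config.error_rate}")
    pos = {
        "n_sites": config.n_sites,
        "n_cells": config.n_cells,
        "n_panels": config.n_panels,
        "cord_cells_per_panel": config.cord_cells_per_panel,
        "min_sites": config.min_sites,
        "n_genes": config.n_genes,
        "n_expr_cells": config.n_expr_cells,
        "min_genes": config.min_genes,
    }
    for name, val in pos.items():
        if val < 1:
            v.append(f"{name} must be >= 1, got {val}")
    if config.criterion not in ("accuracy", "youden"):
        v.append(f"criterion must be accuracy|youden, got {config.criterion!r}")
    if config.difference_mode not in ("alt_support", "allele_presence"):
        v.append(f"unknown difference_mode {config.difference_mode!r}")
    if config.feature_space not in ("panel", "chrom"):
        v.append(f"feature_space must be panel|chrom, got {config.feature_space!r}")
    if not config.simulate:
        for name in ("trio_vcf", "observations_tsv", "labels_tsv"):
            path = getattr(config, name)
            if path is None:
                v.append(f"simulate=False requires {name}")
            elif not os.path.exists(path):
                v.append(f"{name} does not exist: {path}")
    return v


@dataclass
class RunManifest:
    seed: int = 0
    stages: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: dict[str, str], t0: float, seed: int):
        digests = {}
        for name, path in outputs.items():
            with open(path, "rb") as fh:
                digests[name] = hashlib.sha256(fh.read()).hexdigest()
        self.stages.append(
            {
                "stage": stage,
                "seed": seed,
                "outputs": {k: str(v) for k, v in outputs.items()},
                "sha256": digests,
                "wall_s": round(time.time() - t0, 3),
            }
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"seed": self.seed, "stages": self.stages, "metrics": self.metrics},
                fh,
                indent=2,
            )


def run_demux_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full origin-inference run described by ``config``.

    Raises :class:`ConfigError` before any stage runs if validation fails;
    a stage failure propagates with the stage named, partial outputs kept.
    """
    violations = validate_config(config)
    if violations:
        raise ConfigError(violations)
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = RunManifest(seed=config.seed)
    all_metrics: dict = {}

    for section in config.sections:
        sec_dir = os.path.join(config.out_dir, section)
        os.makedirs(sec_dir, exist_ok=True)
        sseed = spawn_seed(config.seed, f"section:{section}")

        # --- genotypes -----------------------------------------------------
        t0 = time.time()
        if config.simulate:
            trio = simulate_trio_genotypes(
                config.n_sites,
                config.informative_fraction,
                seed=spawn_seed(sseed, "trio"),
            )
        else:
            trio = mio.read_trio_vcf(config.trio_vcf)
        trio_path = os.path.join(sec_dir, "trio.vcf")
        mio.write_trio_vcf(trio, trio_path)
        manifest.record(f"{section}/trio", {"trio_vcf": trio_path}, t0, sseed)
        log.info("stage=trio section=%s n_sites=%d", section, trio.n_sites)

        # --- variant hard filtering (annotated records) --------------------
        t0 = time.time()
        records, _ = simulate_variant_records(
            config.n_variant_records,
            config.filter_profile,
            seed=spawn_seed(sseed, "variants"),
        )
        verdicts = filter_records(records, config.filter_profile)
        filt_path = os.path.join(sec_dir, "variants.filtered.vcf")
        mio.write_variant_vcf(records, filt_path, verdicts)
        manifest.record(f"{section}/variant_filter", {"vcf": filt_path}, t0, sseed)

        # --- fetal reference ----------------------------------------------
        t0 = time.time()
        sites_spec = {
            "dist": "negbin",
            "mean": config.cord_mean_sites,
            "dispersion": config.sites_dispersion,
        }
        cord = {
            f"cord{k}": simulate_cell_allele_counts(
                trio,
                config.cord_cells_per_panel,
                fetal_fraction=1.0,
                sites_per_cell=sites_spec,
                error_rate=config.error_rate,
                seed=spawn_seed(sseed, f"cord{k}"),
            )
            for k in range(config.n_panels)
        }
        reference = panels_from_cord_cells(
            cord, min_support=config.panel_min_support, section_id=section
        )
        ref_dir = os.path.join(sec_dir, "reference")
        mio.write_reference_tsv(reference, ref_dir)
        manifest.record(
            f"{section}/reference",
            {
                label: os.path.join(ref_dir, f"{label}.tsv")
                for label in reference.panel_names
            },
            t0,
            sseed,
        )

        # --- cells and features --------------------------------------------
        t0 = time.time()
        if config.simulate:
            obs = simulate_cell_allele_counts(
                trio,
                config.n_cells,
                fetal_fraction=config.fetal_fraction,
                sites_per_cell={
                    "dist": "negbin",
                    "mean": config.mean_sites_per_cell,
                    "dispersion": config.sites_dispersion,
                },
                error_rate=config.error_rate,
                seed=spawn_seed(sseed, "cells"),
            )
            labels = obs.truth
        else:
            df = mio.read_observations_tsv(config.observations_tsv, trio)
            labels = mio.read_labels_tsv(config.labels_tsv)
            from .simulate import CellAlleleObservations

            obs = CellAlleleObservations(
                records=df[["cell", "site_idx", "allele", "depth"]],
                truth=labels,
            )
        obs_path = os.path.join(sec_dir, "observations.tsv")
        mio.write_observations_tsv(obs, trio, obs_path)
        site_chroms = dict(enumerate(trio.sites["chrom"]))
        drm = compute_difference_ratios(
            obs,
            reference,
            min_sites=config.min_sites,
            mode=config.difference_mode,
            features=config.feature_space,
            site_chroms=site_chroms if config.feature_space == "chrom" else None,
        )
        manifest.record(f"{section}/features", {"observations": obs_path}, t0, sseed)

        # --- train / classify / evaluate ------------------------------------
        t0 = time.time()
        rng = np.random.default_rng(spawn_seed(sseed, "split"))
        cells = np.asarray(labels.index)
        perm = rng.permutation(len(cells))
        n_train = int(round(config.train_fraction * len(cells)))
        train, test = cells[perm[:n_train]], cells[perm[n_train:]]
        model = CellOriginModel(drm, labels.loc[train], ridge=config.ridge)
        res = model.fit(criterion=config.criterion, cap=config.cap)
        calls = res.predict(drm)
        metrics = evaluate_calls(calls.loc[test], labels.loc[test])

        calls_out = calls.copy()
        calls_out.insert(0, "section", section)
        calls_path = os.path.join(sec_dir, "calls.tsv")
        calls_out.rename_axis("cell").to_csv(calls_path, sep="\t")
        model_path = os.path.join(sec_dir, "model.json")
        res.save(model_path)
        table_path = os.path.join(sec_dir, "threshold_metrics.tsv")
        res.metrics_table.to_csv(table_path, sep="\t", index=False)
        metrics_path = os.path.join(sec_dir, "metrics.json")
        with open(metrics_path, "w") as fh:
            json.dump(metrics, fh, indent=2)
        manifest.record(
            f"{section}/classify",
            {
                "calls": calls_path,
                "model": model_path,
                "thresholds": table_path,
                "metrics": metrics_path,
            },
            t0,
            sseed,
        )
        all_metrics[section] = metrics
        log.info(
            "stage=classify section=%s accuracy=%s unknown=%.3f",
            section,
            metrics["accuracy"],
            metrics["unknown_fraction"],
        )

    # --- expression branch --------------------------------------------------
    if config.run_expression:
        from .qc import call_lr_pairs, run_qc

        t0 = time.time()
        eseed = spawn_seed(config.seed, "expression")
        adata = simulate_expression_matrix(
            config.n_genes,
            config.n_expr_cells,
            genes_per_cell={"dist": "negbin", "mean": 1200, "dispersion": 8},
            mito_fraction={"dist": "beta", "a": 2.0, "b": 38.0},
            seed=eseed,
        )
        adata.obs["cell_type"] = np.asarray(["typeA", "typeB", "typeC"])[
            np.arange(adata.n_obs) % 3
        ]
        filtered, report = run_qc(
            adata,
            min_cell_fraction=config.min_cell_fraction,
            min_genes=config.min_genes,
            max_mito=config.max_mito,
        )
        expr_dir = os.path.join(config.out_dir, "expression")
        mio.write_expression_mtx(filtered, expr_dir)
        qc_path = os.path.join(expr_dir, "qc_report.json")
        with open(qc_path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        half = min(20, filtered.n_vars // 2)
        pairs = pd.DataFrame(
            {
                "ligand": list(filtered.var_names[:half]),
                "receptor": list(filtered.var_names[half : 2 * half]),
            }
        )
        lr = call_lr_pairs(
            filtered, "cell_type", pairs, min_prevalence=config.lr_min_prevalence
        )
        lr_path = os.path.join(expr_dir, "lr_calls.tsv")
        lr.to_csv(lr_path, sep="\t", index=False)
        manifest.record(
            "expression/qc_lr",
            {"qc_report": qc_path, "lr_calls": lr_path},
            t0,
            eseed,
        )
        all_metrics["expression"] = {
            "n_cells_after_qc": int(filtered.n_obs),
            "n_genes_after_qc": int(filtered.n_vars),
            "n_lr_calls": int(len(lr)),
        }

    manifest.metrics = all_metrics
    manifest.save(os.path.join(config.out_dir, "manifest.json"))
    return manifest
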