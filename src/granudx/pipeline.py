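"""End-to-end orchestration mirroring the analysis order of the study design:

log2 transform -> ComBat (for PCA/heatmap only) -> proteomic-ruler copy
numbers -> batch-blocked differential expression per disease contrast (on
the *unadjusted* matrix) -> single-patient Gaussian anomaly reports ->
cohort profiling.  Every artifact written is listed in a manifest JSON
with its SHA-256 hash, so a rerun under the same seed can be verified
file-by-file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as gio
from .containers import ExpressionMatrix, SampleTable
from .diffexp import DesignSpec, classify_and_summarize, run_differential_expression
from .outlier import fit_healthy_gaussians, rank_anomalies
from .preprocess import combat_adjust, log2_transform
from .profiling import pca_profiles, zscore_vs_healthy
from .ruler import RulerConstants, copies_per_cell, mean_log10_copies, n_to_fraction

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    matrix_path: str
    samples_path: str
    peptides_path: str
    annotations_path: str
    out_dir: str
    contrasts: list[str] = field(default_factory=list)  # case groups vs healthy
    patients: list[str] = field(default_factory=list)  # sample ids to diagnose
    de_padj: float = 0.01
    de_fc: float = 2.0
    dx_threshold: float = 0.01
    min_peptides_de: int = 2
    min_peptides_dx: int = 3
    dna_mass_per_cell: float = 6.5e-12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_padj", "dx_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.de_fc < 1:
            raise ValueError("de_fc must be >= 1")

    @classmethod
    def from_json(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the artifact manifest (also written to disk).

    Any stage failure raises after tagging partial outputs with a
    ``.partial`` marker file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "artifacts": {}, "inputs": {}}
    partial_marker = out / ".partial"
    partial_marker.touch()

    def record(stage: str, path: Path, t0: float) -> None:
        manifest["artifacts"][str(path.relative_to(out))] = _sha256(path)
        manifest["stages"].setdefault(stage, {})["seconds"] = round(
            time.perf_counter() - t0, 3
        )

    for key, p in (
        ("matrix", config.matrix_path),
        ("samples", config.samples_path),
        ("peptides", config.peptides_path),
        ("annotations", config.annotations_path),
    ):
        manifest["inputs"][key] = _sha256(Path(p))

    stage = "load"
    try:
        t0 = time.perf_counter()
        matrix = gio.read_expression_matrix(config.matrix_path, scale="linear")
        samples = gio.read_sample_table(config.samples_path)
        peptides = gio.read_peptide_support(config.peptides_path)
        annotations = gio.read_annotation_table(config.annotations_path)
        gene_symbols = {p: a.gene_symbol for p, a in annotations.items()}
        logger.info("loaded %d proteins × %d samples", *matrix.shape)

        stage = "log2"
        log2 = log2_transform(matrix)

        stage = "combat"
        t = time.perf_counter()
        adjusted, _model = combat_adjust(log2, samples)
        gio.write_expression_matrix(adjusted, out / "matrix_combat.tsv")
        record("combat", out / "matrix_combat.tsv", t)

        stage = "ruler"
        t = time.perf_counter()
        constants = RulerConstants(dna_mass_per_cell=config.dna_mass_per_cell)
        copies = copies_per_cell(matrix, annotations, constants)
        gio.write_expression_matrix(copies, out / "copies.tsv")
        healthy = samples.samples_in_group("healthy")
        mean_copies = copies.values[healthy].mean(axis=1)
        manifest["stages"]["ruler"] = {
            "n_to_half_abundance": n_to_fraction(mean_copies.to_numpy(), 0.5)
        }
        record("ruler", out / "copies.tsv", t)

        stage = "diffexp"
        ml10 = mean_log10_copies(copies, healthy)
        contrasts = config.contrasts or [
            g for g in samples.data["group"].unique() if g != "healthy"
        ]
        for case in contrasts:
            t = time.perf_counter()
            design = DesignSpec(
                case=case, reference="healthy",
                min_peptides=config.min_peptides_de,
            )
            de = run_differential_expression(
                log2, samples, design, peptides,
                padj_threshold=config.de_padj,
                lfc_threshold=float(np.log2(config.de_fc)),
                gene_symbols=gene_symbols,
            )
            summary = classify_and_summarize(de, ml10)
            path = out / f"de_{case}.tsv"
            de.to_csv(path, sep="\t")
            manifest["stages"][f"diffexp:{case}"] = {
                "n_under": summary["n_under"],
                "n_over": summary["n_over"],
            }
            record(f"diffexp:{case}", path, t)

        stage = "diagnose"
        t = time.perf_counter()
        models = fit_healthy_gaussians(
            log2, samples, peptides, min_peptides=config.min_peptides_dx
        )
        for patient in config.patients or samples.data.loc[
            samples.data["group"] != "healthy", "sample_id"
        ]:
            report = rank_anomalies(
                log2, patient, models, copies=copies,
                healthy_sample_ids=healthy,
                threshold=config.dx_threshold,
                gene_symbols=gene_symbols,
            )
            jpath = out / f"diagnosis_{patient}.json"
            report.to_json(jpath)
            report.rows.to_csv(out / f"diagnosis_{patient}.tsv", sep="\t")
            record("diagnose", jpath, t)
            manifest["artifacts"][f"diagnosis_{patient}.tsv"] = _sha256(
                out / f"diagnosis_{patient}.tsv"
            )

        stage = "profiling"
        t = time.perf_counter()
        pca = pca_profiles(adjusted)
        pca.scores.to_csv(out / "pca.tsv", sep="\t")
        hm = zscore_vs_healthy(adjusted, samples)
        hm["zscores"].to_csv(out / "heatmap_matrix.tsv", sep="\t")
        with open(out / "orders.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "row_order": [str(x) for x in hm["row_order"]],
                    "col_order": [str(x) for x in hm["col_order"]],
                    "pca_variance_fractions": [
                        float(v) for v in pca.variance_fractions
                    ],
                },
                fh,
                indent=2,
            )
        for name in ("pca.tsv", "heatmap_matrix.tsv", "orders.json"):
            manifest["artifacts"][name] = _sha256(out / name)
        manifest["stages"]["profiling"] = {
            "seconds": round(time.perf_counter() - t, 3)
        }
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    partial_marker.unlink(missing_ok=True)
    return manifest
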