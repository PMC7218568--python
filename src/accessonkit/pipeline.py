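"""End-to-end pipeline: io -> accessons -> clustering, with a manifest.

Every stage writes its intermediate artifacts into the run directory and
records parameters, seeds, and output paths in ``manifest.json`` so any
stage can be reproduced in isolation.  A failing stage aborts with its
name, leaving a ``.partial`` marker next to the manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import __version__
from .accesson_core import (
    build_accesson_matrix,
    build_peak_graph,
    embed_peaks,
    group_peaks,
    normalize_counts,
)
from .cell_clustering import build_cell_graph, louvain_cluster
from .errors import AccessonKitError
from .matrix_io import (
    compute_cell_qc,
    filter_cells,
    filter_peaks,
    read_fragment_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and algorithm parameters of a pipeline run."""

    mtx: str
    peaks: str
    barcodes: str
    outdir: str
    totals: str | None = None      # optional per-cell total-fragment TSV
    pf_cutoff: float = 0.0
    nf_cutoff: float = 0.0
    min_qscore: float = 0.0
    max_peaks: int | None = None
    n_accessons: int = 600
    knn: int = 10
    n_pcs: int = 40
    norm: str = "zscore"
    neighbors: int = 20
    resolution: float = 1.0
    seed: int = 0
    orientation: str | None = None


def run_pipeline(config: RunConfig) -> dict:
    """Execute io -> accesson -> cluster and return the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    partial = outdir / "manifest.partial"
    partial.touch()
    manifest: dict = {
        "tool": "accessonkit",
        "version": __version__,
        "parameters": asdict(config),
        "stages": {},
    }
    stage = "io"
    try:
        matrix = read_fragment_matrix(
            config.mtx, config.peaks, config.barcodes, config.orientation)
        if config.min_qscore > 0 or config.max_peaks is not None:
            matrix = filter_peaks(matrix, config.min_qscore, config.max_peaks)
        if config.pf_cutoff > 0 or config.nf_cutoff > 0:
            totals = None
            if config.totals is not None:
                tot = pd.read_csv(config.totals, sep="\t")
                totals = tot.set_index(tot.columns[0]).loc[
                    matrix.barcodes].iloc[:, 0].to_numpy(float)
            qc = compute_cell_qc(matrix, totals=totals)
            matrix = filter_cells(matrix, qc, config.pf_cutoff, config.nf_cutoff)
        manifest["stages"]["io"] = {
            "n_cells": matrix.n_cells, "n_peaks": matrix.n_peaks}

        stage = "accesson"
        norm = normalize_counts(matrix)
        embedding = embed_peaks(norm, config.n_pcs)
        graph = build_peak_graph(embedding, config.knn)
        assignment = group_peaks(embedding, graph, config.n_accessons)
        M = build_accesson_matrix(matrix, assignment, config.norm)
        assignment_path = outdir / "accesson_assignment.tsv"
        pd.DataFrame({"peak_index": np.arange(matrix.n_peaks),
                      "accesson_id": assignment.labels}).to_csv(
            assignment_path, sep="\t", index=False)
        raw_path = outdir / "accesson_raw.mtx"
        scipy.io.mmwrite(str(raw_path), sp.coo_matrix(M.raw))
        norm_path = outdir / "accesson_normalized.tsv"
        pd.DataFrame(M.normalized, index=matrix.barcodes).to_csv(
            norm_path, sep="\t", header=False)
        manifest["stages"]["accesson"] = {
            "n_accessons": assignment.n_accessons,
            "assignment": str(assignment_path),
            "raw_matrix": str(raw_path),
            "normalized_matrix": str(norm_path),
        }

        stage = "cluster"
        cell_graph = build_cell_graph(M, config.neighbors)
        labels = louvain_cluster(cell_graph, config.resolution, config.seed)
        labels_path = outdir / "cell_clusters.tsv"
        pd.DataFrame({"barcode": matrix.barcodes,
                      "cluster": labels.labels}).to_csv(
            labels_path, sep="\t", index=False)
        manifest["stages"]["cluster"] = {
            "n_clusters": labels.n_clusters, "labels": str(labels_path)}
    except Exception as exc:
        raise AccessonKitError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    partial.unlink(missing_ok=True)
    return manifest
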