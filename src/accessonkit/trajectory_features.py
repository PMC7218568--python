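"""Low-dimensional accesson features for pseudotime engines, and curves.

Trajectory construction itself is delegated to external tools (Monocle,
SPRING); this module produces what they consume — the top principal
components of the accesson matrix per cell — and summarizes per-cell
scores along an externally supplied pseudotime ordering as binned curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accesson_core import AccessonMatrix, normalize_rows
from .errors import ParameterError

DEPTH_CORR_CUTOFF = 0.8


@dataclass
class CellEmbedding:
    """Cells x n_pcs coordinates with per-PC depth correlations."""

    coords: np.ndarray
    explained_variance_ratio: np.ndarray
    depth_correlations: np.ndarray


def accesson_pca(
    M: "AccessonMatrix | np.ndarray",
    n_pcs: int = 5,
    use: str = "probability",
    drop_depth_pc: bool = False,
) -> CellEmbedding:
    """PCA of cells over accesson columns.

    ``use`` selects the matrix fed to PCA: per-cell ``probability``
    rows (default; depth cancels), the stored ``normalized`` form, or
    ``raw`` counts.  Each PC's Pearson correlation with per-cell total
    counts is reported; with ``drop_depth_pc`` the single component most
    correlated with depth (|r| > 0.8) is removed and the next component
    appended, mirroring the practice of hiding a pure sequencing-depth
    axis from trajectory views.
    """
    if n_pcs < 2:
        raise ParameterError("n_pcs must be >= 2")
    if isinstance(M, AccessonMatrix):
        raw = M.raw
        if use == "probability":
            X = normalize_rows(raw, "probability")
        elif use == "normalized":
            X = M.normalized
        elif use == "raw":
            X = raw
        else:
            raise ParameterError(f"unknown matrix choice {use!r}")
        depth = raw.sum(axis=1)
    else:
        X = np.asarray(M, dtype=float)
        depth = X.sum(axis=1)
    n_cells, n_acc = X.shape
    k = min(n_pcs + (1 if drop_depth_pc else 0), min(n_cells, n_acc))
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    coords = U[:, :k] * S[:k]
    flips = np.sign(coords[np.abs(coords).argmax(axis=0), np.arange(k)])
    flips[flips == 0] = 1.0
    coords = coords * flips
    var = S ** 2
    evr = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    corr = np.zeros(k)
    if depth.std() > 0:
        for c in range(k):
            if coords[:, c].std() > 0:
                corr[c] = np.corrcoef(coords[:, c], depth)[0, 1]
    if drop_depth_pc:
        over = np.flatnonzero(np.abs(corr) > DEPTH_CORR_CUTOFF)
        if over.size:
            drop = over[np.argmax(np.abs(corr[over]))]
            keep = [c for c in range(k) if c != drop][:n_pcs]
        else:
            keep = list(range(min(n_pcs, k)))
        coords, evr, corr = coords[:, keep], evr[keep], corr[keep]
    else:
        coords, evr, corr = coords[:, :n_pcs], evr[:n_pcs], corr[:n_pcs]
    return CellEmbedding(coords, evr, corr)


def score_along_pseudotime(
    values: "np.ndarray | pd.DataFrame",
    pseudotime: np.ndarray,
    branch: np.ndarray | None = None,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Equal-count binned mean +/- SEM of per-cell scores along pseudotime.

    ``values`` is a per-cell vector or a cells x scores matrix; cells are
    ordered by pseudotime within each branch and split into ``n_bins``
    near-equal-count bins.  Branches with fewer cells than bins get fewer
    bins (warned); branches with < 2 cells are skipped.
    """
    vals = pd.DataFrame(values)
    pt = np.asarray(pseudotime, dtype=float)
    if not np.all(np.isfinite(pt)):
        raise ParameterError("pseudotime must be finite")
    if branch is None:
        branch = np.zeros(pt.size, dtype=np.int64)
    branch = np.asarray(branch)
    rows = []
    for b in np.unique(branch):
        idx = np.flatnonzero(branch == b)
        if idx.size < 2:
            warnings.warn(f"branch {b!r} has < 2 cells; skipped")
            continue
        bins = n_bins
        if idx.size < n_bins:
            warnings.warn(
                f"branch {b!r} has {idx.size} cells < {n_bins} bins; reduced")
            bins = idx.size
        order = idx[np.argsort(pt[idx], kind="stable")]
        for bin_id, chunk in enumerate(np.array_split(order, bins)):
            sub = vals.iloc[chunk]
            mean = sub.mean(axis=0)
            sem = sub.std(axis=0, ddof=1) / np.sqrt(len(chunk)) \
                if len(chunk) > 1 else mean * 0.0
            for score_name in vals.columns:
                rows.append({
                    "branch": b,
                    "bin": bin_id,
                    "pseudotime_center": float(pt[chunk].mean()),
                    "score": score_name,
                    "mean": float(mean[score_name]),
                    "sem": float(sem[score_name]),
                    "n_cells": len(chunk),
                })
    return pd.DataFrame(rows)
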