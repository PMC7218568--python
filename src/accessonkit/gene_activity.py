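"""TSS-window gene activity scores and differential analysis.

A gene's raw score in a cell is the mean raw fragment count over all peaks
whose interval intersects the gene's TSS +/- window (20 kb by default);
normalization rescales each gene column to a fixed total of 10,000 across
cells so scores are on a scale comparable to scRNA-seq expression.
Differential genes between a target cluster and the rest are found by a
two-sided Welch t-test with Benjamini-Hochberg correction and a
pseudocounted fold-change filter.  For very sparse data a second path
tests accessons first and reports the genes near peaks of the significant
accessons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .accesson_core import AccessonAssignment, AccessonMatrix
from .cell_clustering import ClusterLabels
from .errors import ParameterError, ValidationError
from .matrix_io import FragmentCountMatrix, PeakSet

logger = logging.getLogger(__name__)

SCORE_SCALE = 10_000
FC_PSEUDOCOUNT = 0.01


@dataclass
class GeneScoreMatrix:
    """Raw and normalized gene activity scores (cells x genes DataFrames)."""

    raw: pd.DataFrame
    normalized: pd.DataFrame


def map_peaks_to_genes(
    peaks: PeakSet, tss_table: pd.DataFrame, window: int = 20_000
) -> dict[str, np.ndarray]:
    """Map each gene to the peak indices intersecting TSS +/- window.

    Intervals are half-open; a peak may map to several genes.  Genes with
    no peak in range are omitted from the map.
    """
    if window <= 0:
        raise ParameterError("window must be positive")
    mapping: dict[str, np.ndarray] = {}
    for chrom, grp in tss_table.groupby("chrom"):
        on_chrom = np.flatnonzero(peaks.chrom == chrom)
        if on_chrom.size == 0:
            continue
        starts, ends = peaks.start[on_chrom], peaks.end[on_chrom]
        for gene, tss in zip(grp["gene"], grp["tss"]):
            lo, hi = int(tss) - window, int(tss) + window
            hit = on_chrom[(starts < hi) & (ends > lo)]
            if hit.size:
                mapping[gene] = hit
    if not mapping:
        warnings.warn("no peak intersects any gene window; map is empty")
    return mapping


def gene_scores(
    matrix: FragmentCountMatrix,
    gene_map: dict[str, np.ndarray],
    normalize: bool = True,
) -> GeneScoreMatrix:
    """Mean in-window peak count per gene, optionally column-normalized.

    S_ij = mean over gene j's mapped peaks of B_ij;
    S'_ij = S_ij * 10000 / sum_i S_ij per gene column (zero columns stay
    zero).
    """
    genes = list(gene_map)
    raw = np.zeros((matrix.n_cells, len(genes)))
    for col, gene in enumerate(genes):
        idx = np.asarray(gene_map[gene])
        raw[:, col] = np.asarray(
            matrix.counts[:, idx].mean(axis=1)).ravel()
    raw_df = pd.DataFrame(raw, index=matrix.barcodes, columns=genes)
    if normalize:
        col_sums = raw.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(col_sums > 0, raw * SCORE_SCALE / col_sums, 0.0)
    else:
        norm = raw.copy()
    norm_df = pd.DataFrame(norm, index=matrix.barcodes, columns=genes)
    return GeneScoreMatrix(raw_df, norm_df)


def _one_vs_rest(
    values: np.ndarray,
    labels: np.ndarray,
    target_cluster,
    feature_names,
    p_cutoff: float,
    fc_cutoff: float,
) -> pd.DataFrame:
    """Welch t-test + BH + pseudocounted fold change, target vs rest."""
    in_target = labels == target_cluster
    n_t, n_r = int(in_target.sum()), int((~in_target).sum())
    if n_t < 3 or n_r < 3:
        raise ValidationError(
            f"cluster {target_cluster!r} needs >= 3 cells on both sides "
            f"(target={n_t}, rest={n_r})")
    a, b = values[in_target], values[~in_target]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p_val = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t_stat = np.nan_to_num(t_stat, nan=0.0)
    p_val = np.where(np.isnan(p_val), 1.0, p_val)
    _, p_adj, _, _ = multipletests(p_val, method="fdr_bh")
    fold = (a.mean(axis=0) + FC_PSEUDOCOUNT) / (b.mean(axis=0) + FC_PSEUDOCOUNT)
    table = pd.DataFrame({
        "feature": list(feature_names),
        "cluster": target_cluster,
        "t_statistic": t_stat,
        "p_value": p_val,
        "p_adjusted": p_adj,
        "fold_change": fold,
    })
    table["significant"] = (table["p_adjusted"] <= p_cutoff) & (
        table["fold_change"] >= fc_cutoff)
    return table


def differential_genes(
    scores: GeneScoreMatrix,
    labels: "ClusterLabels | np.ndarray",
    target_cluster,
    p_cutoff: float = 0.05,
    fc_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Differential genes of one cluster vs all other cells."""
    lab = labels.labels if isinstance(labels, ClusterLabels) else np.asarray(labels)
    return _one_vs_rest(
        scores.normalized.to_numpy(), lab, target_cluster,
        scores.normalized.columns, p_cutoff, fc_cutoff)


def differential_genes_via_accessons(
    M: AccessonMatrix,
    assignment: AccessonAssignment,
    labels: "ClusterLabels | np.ndarray",
    peaks: PeakSet,
    tss_table: pd.DataFrame,
    target_cluster,
    p_cutoff: float = 0.05,
    fc_cutoff: float = 2.0,
    window: int = 20_000,
) -> list[str]:
    """Sparse-data path: test accessons, then name genes near their peaks.

    The one-vs-rest test runs on per-cell probability-scaled accesson
    counts (rows rescaled to a 10,000 total so fold changes are
    depth-independent); all peaks of significant accessons are collected
    and every gene whose TSS window intersects any of them is returned.
    """
    lab = labels.labels if isinstance(labels, ClusterLabels) else np.asarray(labels)
    row_sums = M.raw.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(row_sums > 0, M.raw * SCORE_SCALE / row_sums, 0.0)
    table = _one_vs_rest(
        values, lab, target_cluster,
        range(M.raw.shape[1]), p_cutoff, fc_cutoff)
    hits = table.loc[table["significant"], "feature"].to_numpy()
    if hits.size == 0:
        return []
    peak_idx = np.flatnonzero(np.isin(assignment.labels, hits))
    gene_map = map_peaks_to_genes(peaks, tss_table, window)
    return sorted(g for g, idx in gene_map.items()
                  if np.intersect1d(idx, peak_idx).size > 0)
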