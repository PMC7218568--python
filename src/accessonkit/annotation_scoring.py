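"""Cluster association, weighted annotation scores, super-enhancer calling.

Three downstream uses of the accesson decomposition:

* Fisher's exact test on shared differential genes associates cell
  clusters found from chromatin accessibility with clusters found from
  transcriptomes; the resulting -log(P) matrix is z-scored by row and
  then by column for display.
* Term x accesson weight matrices (GO-term or motif significance,
  produced by external enrichment services) are multiplied by the
  accesson count matrix to score every term in every cell.
* Genomic windows unusually dominated by peaks of a single accesson are
  reported as candidate super-enhancers under an empirical genome-wide
  null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .accesson_core import AccessonAssignment, AccessonMatrix
from .errors import ParameterError, ValidationError
from .matrix_io import PeakSet

logger = logging.getLogger(__name__)


@dataclass
class AssociationMatrix:
    """-log(P) Fisher association between two cluster sets, plus z-scores."""

    neglogp: pd.DataFrame
    z_rows: pd.DataFrame
    z_cols: pd.DataFrame


@dataclass
class SuperEnhancerCall:
    """A merged window where one accesson dominates the local peak set."""

    chrom: str
    start: int
    end: int
    accesson: int
    n_peaks_in_window: int
    fraction: float
    p_value: float


def _zscore(arr: np.ndarray, axis: int) -> np.ndarray:
    mean = arr.mean(axis=axis, keepdims=True)
    sd = arr.std(axis=axis, keepdims=True)  # population SD
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sd > 0, (arr - mean) / sd, 0.0)


def fisher_association(
    diff_sets_a: dict, diff_sets_b: dict, universe: set,
    alternative: str = "greater", log_base: str = "natural",
    z_order: str = "rows-then-cols",
) -> AssociationMatrix:
    """Fisher's exact association between two families of gene sets.

    For clusters a and b with differential gene sets A_a and B_b inside a
    common ``universe``: G11 = |A_a & B_b|, G12 = |A_a - B_b|,
    G21 = |B_b - A_a|, G22 = the remaining universe genes.  One-sided
    (enrichment) P values fill the matrix A_ab = -log(p); the matrix is
    z-scored per row and then per column (order switchable).
    """
    if len(universe) < 10:
        raise ValidationError("universe must contain at least 10 genes")
    universe = set(universe)
    for name, sets in (("A", diff_sets_a), ("B", diff_sets_b)):
        for key, s in sets.items():
            if not set(s) <= universe:
                raise ValidationError(
                    f"differential set {name}[{key!r}] is not within universe")
    rows, cols = list(diff_sets_a), list(diff_sets_b)
    neglogp = np.zeros((len(rows), len(cols)))
    for i, a in enumerate(rows):
        set_a = set(diff_sets_a[a])
        for j, b in enumerate(cols):
            set_b = set(diff_sets_b[b])
            g11 = len(set_a & set_b)
            g12 = len(set_a - set_b)
            g21 = len(set_b - set_a)
            g22 = len(universe) - g11 - g12 - g21
            if g22 < 0:
                raise ValidationError("sets exceed universe")
            _, p = stats.fisher_exact([[g11, g12], [g21, g22]],
                                      alternative=alternative)
            neglogp[i, j] = -(np.log(p) if log_base == "natural" else np.log10(p))
    neglogp = np.maximum(neglogp, 0.0)  # clip -log(1) == -0.0
    if z_order == "rows-then-cols":
        z_rows = _zscore(neglogp, axis=1)
        z_cols = _zscore(z_rows, axis=0)
    elif z_order == "cols-then-rows":
        z_rows = _zscore(neglogp, axis=0)
        z_cols = _zscore(z_rows, axis=1)
    else:
        raise ParameterError(f"unknown z_order {z_order!r}")
    wrap = lambda m: pd.DataFrame(m, index=rows, columns=cols)
    return AssociationMatrix(wrap(neglogp), wrap(z_rows), wrap(z_cols))


def weighted_annotation_scores(
    weights: pd.DataFrame, M: "AccessonMatrix | np.ndarray"
) -> pd.DataFrame:
    """Score terms per cell: (terms x accessons) @ (accessons x cells).

    ``weights`` holds -log significance of each term (GO term or motif) on
    each accesson's peaks; ``M`` is the accesson count matrix (cells x
    accessons).  Each term row of the product is z-scored (population SD,
    constant rows to zero).
    """
    counts = M.raw if isinstance(M, AccessonMatrix) else np.asarray(M, float)
    W = weights.to_numpy(float)
    if W.shape[1] != counts.shape[1]:
        raise ParameterError(
            f"weights have {W.shape[1]} accesson columns but the accesson "
            f"matrix has {counts.shape[1]}")
    scores = W @ counts.T  # terms x cells
    return pd.DataFrame(_zscore(scores, axis=1), index=weights.index)


def call_super_enhancers(
    peaks: PeakSet,
    assignment: AccessonAssignment,
    window: int = 1_000_000,
    step: int = 100_000,
    p_cutoff: float = 0.01,
    min_peaks: int = 10,
) -> list[SuperEnhancerCall]:
    """Find windows where many peaks belong to one accesson.

    A window of ``window`` bp slides by ``step`` along each chromosome.
    For every (window, accesson) pair the member fraction is the number of
    that accesson's peaks in the window (by midpoint) over all peaks in
    the window.  The null pool collects the fractions of every accesson
    present in every window holding at least ``min_peaks`` peaks in total;
    candidates additionally need ``min_peaks`` member peaks.  The
    empirical P value of a candidate is the +1-smoothed upper-tail rank of
    its fraction in the pool; calls below ``p_cutoff`` are reported, with
    overlapping windows of the same accesson merged into one interval.
    """
    if len(assignment.labels) != len(peaks):
        raise ParameterError("assignment does not cover the peak set")
    mids = peaks.midpoints()
    pool: list[float] = []
    candidates = []  # (chrom, wstart, wend, accesson, n_member, fraction)
    for chrom in np.unique(peaks.chrom):
        idx = np.flatnonzero(peaks.chrom == chrom)
        order = idx[np.argsort(mids[idx], kind="stable")]
        pos = mids[order]
        labels = assignment.labels[order]
        last = int(pos[-1])
        for wstart in range(0, last + 1, step):
            wend = wstart + window
            lo = np.searchsorted(pos, wstart, side="left")
            hi = np.searchsorted(pos, wend, side="left")
            total = hi - lo
            if total < min_peaks:
                continue
            accs, counts = np.unique(labels[lo:hi], return_counts=True)
            fracs = counts / total
            pool.extend(fracs.tolist())
            for acc, cnt, frac in zip(accs, counts, fracs):
                if cnt >= min_peaks:
                    candidates.append(
                        (str(chrom), wstart, wend, int(acc), int(cnt), float(frac)))
    if not candidates:
        logger.info("no window holds %d peaks of a single accesson", min_peaks)
        return []
    pool_arr = np.sort(np.asarray(pool))
    n_pool = pool_arr.size
    calls: list[SuperEnhancerCall] = []
    for chrom, wstart, wend, acc, cnt, frac in candidates:
        n_ge = n_pool - np.searchsorted(pool_arr, frac, side="left")
        p = n_ge / (n_pool + 1)
        if p < p_cutoff:
            calls.append(SuperEnhancerCall(chrom, wstart, wend, acc, cnt, frac, p))
    return _merge_calls(calls)


def _merge_calls(calls: list[SuperEnhancerCall]) -> list[SuperEnhancerCall]:
    """Union overlapping same-accesson windows, keeping the strongest stats."""
    merged: list[SuperEnhancerCall] = []
    key = lambda c: (c.chrom, c.accesson, c.start)
    for call in sorted(calls, key=key):
        prev = merged[-1] if merged else None
        if (prev is not None and prev.chrom == call.chrom
                and prev.accesson == call.accesson and call.start <= prev.end):
            merged[-1] = SuperEnhancerCall(
                prev.chrom, prev.start, max(prev.end, call.end), prev.accesson,
                max(prev.n_peaks_in_window, call.n_peaks_in_window),
                max(prev.fraction, call.fraction),
                min(prev.p_value, call.p_value))
        else:
            merged.append(call)
    return merged


def calls_to_frame(calls: list[SuperEnhancerCall]) -> pd.DataFrame:
    """Tabulate super-enhancer calls (BED-like columns first)."""
    return pd.DataFrame([c.__dict__ for c in calls])
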