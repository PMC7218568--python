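"""Accesson construction: normalize counts, embed peaks, group them.

An *accesson* is a group of peaks whose accessibility fluctuates together
across single cells.  Peaks are embedded by the top principal components of
the depth-normalized count matrix, connected by a K-nearest-neighbor graph,
and merged by Ward agglomeration restricted to graph edges.  Summing raw
fragment counts over each group converts the sparse cells x peaks matrix
into a dense cells x accessons matrix ``M``, normalized per cell (z-score
or probability) into ``M_a`` for downstream clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import AgglomerativeClustering
from sklearn.neighbors import kneighbors_graph

from .errors import ParameterError
from .matrix_io import FragmentCountMatrix

logger = logging.getLogger(__name__)

READS_PER_CELL = 10_000  # library-size target of the per-cell normalization


@dataclass
class NormalizedMatrix:
    """Depth-normalized counts B' = log2(B * 10000 / rowsum + 1), sparse."""

    values: sp.csr_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PeakEmbedding:
    """Per-peak coordinates in the top principal components of B'."""

    coords: np.ndarray  # peaks x n_pcs
    n_pcs: int
    explained_variance_ratio: np.ndarray | None = None


@dataclass
class PeakGraph:
    """Symmetric binary KNN connectivity matrix over peaks (C_peak)."""

    adjacency: sp.csr_matrix
    k: int


@dataclass
class AccessonAssignment:
    """Partition of peaks into accessons: labels in 0..n_accessons-1."""

    labels: np.ndarray
    n_accessons: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        distinct = np.unique(self.labels)
        if distinct.size != self.n_accessons or distinct[0] != 0 \
                or distinct[-1] != self.n_accessons - 1:
            raise ParameterError("accesson labels must be dense 0..n-1")

    def members(self, accesson: int) -> np.ndarray:
        return np.flatnonzero(self.labels == accesson)


@dataclass
class AccessonMatrix:
    """Cells x accessons summed counts M and its per-cell normalization M_a."""

    raw: np.ndarray
    normalized: np.ndarray
    method: str


def normalize_counts(matrix: FragmentCountMatrix) -> NormalizedMatrix:
    """Per-cell depth normalization to a common 10,000-read scale.

    B'_ij = log2(B_ij * 10000 / sum_j' B_ij' + 1).  All-zero cells stay
    all-zero (no division by zero); zero entries map to log2(1) = 0, so
    the result keeps the sparsity pattern of the input.
    """
    counts = sp.csr_matrix(matrix.counts, dtype=float)
    row_sums = np.asarray(counts.sum(axis=1)).ravel()
    scale = np.zeros_like(row_sums)
    nz = row_sums > 0
    scale[nz] = READS_PER_CELL / row_sums[nz]
    out = counts.copy()
    out.data = np.log2(out.data * np.repeat(scale, np.diff(counts.indptr)) + 1.0)
    return NormalizedMatrix(out)


def embed_peaks(norm: NormalizedMatrix, n_pcs: int = 40) -> PeakEmbedding:
    """Project peaks onto the top principal components of B'.

    PCA is taken over the cell dimension: each peak column is centered,
    and a peak's coordinates are the projections of its column onto the
    leading left singular vectors (equivalently rows of V * S).  Signs are
    fixed so each component's largest-magnitude peak coordinate is
    positive, making the embedding deterministic.
    """
    if n_pcs < 1:
        raise ParameterError("n_pcs must be >= 1")
    X = np.asarray(norm.values.todense(), dtype=float)
    n_cells, n_peaks = X.shape
    limit = min(n_cells, n_peaks)
    if n_pcs > limit:
        warnings.warn(f"n_pcs={n_pcs} clipped to min(n_cells, n_peaks)={limit}")
        n_pcs = limit
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    coords = Vt.T[:, :n_pcs] * S[:n_pcs]
    # deterministic sign convention
    flips = np.sign(coords[np.abs(coords).argmax(axis=0), np.arange(n_pcs)])
    flips[flips == 0] = 1.0
    coords = coords * flips
    var = S ** 2
    evr = var[:n_pcs] / var.sum() if var.sum() > 0 else np.zeros(n_pcs)
    return PeakEmbedding(coords, n_pcs, evr)


def build_peak_graph(embedding: PeakEmbedding, k: int = 10) -> PeakGraph:
    """K-nearest-neighbor connectivity of peaks in PC space (C_peak).

    Euclidean distances, self excluded, symmetrized by union.
    """
    n_peaks = embedding.coords.shape[0]
    if k >= n_peaks:
        raise ParameterError(f"k={k} must be < number of peaks ({n_peaks})")
    adj = kneighbors_graph(embedding.coords, n_neighbors=k,
                           mode="connectivity", include_self=False)
    adj = adj.maximum(adj.T).tocsr()
    adj.setdiag(0)
    adj.eliminate_zeros()
    return PeakGraph(adj, k)


def _constrained_ward(
    X: np.ndarray, adjacency: sp.csr_matrix, n_clusters: int
) -> np.ndarray:
    """Ward agglomeration restricted to graph edges, strict about components.

    The clustering runs independently inside each connected component so no
    merge ever crosses a missing edge; the requested cluster count is
    apportioned to components by largest-remainder on component size.
    Returns dense labels 0..n_clusters-1 (or one label per component if the
    graph has more components than requested clusters).
    """
    n = X.shape[0]
    n_comp, comp = connected_components(adjacency, directed=False)
    if n_comp > n_clusters:
        warnings.warn(
            f"constraint graph has {n_comp} components > requested "
            f"{n_clusters} clusters; returning components as clusters")
        return comp.astype(np.int64)
    sizes = np.bincount(comp, minlength=n_comp)
    quota = np.maximum(1, np.floor(n_clusters * sizes / n).astype(int))
    quota = np.minimum(quota, sizes)
    # largest-remainder adjustment to hit n_clusters exactly
    while quota.sum() < n_clusters:
        room = sizes - quota
        cand = np.flatnonzero(room > 0)
        quota[cand[np.argmax(room[cand])]] += 1
    while quota.sum() > n_clusters:
        cand = np.flatnonzero(quota > 1)
        quota[cand[np.argmax(quota[cand])]] -= 1
    labels = np.empty(n, dtype=np.int64)
    offset = 0
    for c in range(n_comp):
        idx = np.flatnonzero(comp == c)
        kc = int(quota[c])
        if kc == 1 or idx.size == 1:
            labels[idx] = offset
        elif kc == idx.size:
            labels[idx] = offset + np.arange(idx.size)
        else:
            sub = adjacency[np.ix_(idx, idx)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = AgglomerativeClustering(
                    n_clusters=kc, linkage="ward", metric="euclidean",
                    connectivity=sub)
                labels[idx] = offset + model.fit_predict(X[idx])
        offset += kc
    return labels


def group_peaks(
    embedding: PeakEmbedding,
    graph: PeakGraph,
    n_accessons: int = 600,
) -> AccessonAssignment:
    """Group peaks into accessons by connectivity-constrained Ward clustering.

    Merges are only permitted along edges of the peak KNN graph; distances
    are Euclidean in PC space with Ward linkage.  A request exceeding the
    peak count is capped; if the graph splits into more components than the
    requested number of accessons, the components themselves are returned
    (with a warning).
    """
    n_peaks = embedding.coords.shape[0]
    if n_accessons < 1:
        raise ParameterError("n_accessons must be >= 1")
    if n_accessons > n_peaks:
        warnings.warn(
            f"n_accessons={n_accessons} capped to peak count {n_peaks}")
        n_accessons = n_peaks
    labels = _constrained_ward(embedding.coords, graph.adjacency, n_accessons)
    n_found = int(labels.max()) + 1
    return AccessonAssignment(labels, n_found)


def build_accesson_matrix(
    matrix: FragmentCountMatrix,
    assignment: AccessonAssignment,
    method: str = "zscore",
) -> AccessonMatrix:
    """Sum raw fragment counts per accesson and normalize each cell row.

    M_ik = sum over peaks j in accesson k of B_ij.  ``method`` selects the
    per-cell normalization of M into M_a: ``probability`` divides each row
    by its sum (all-zero rows stay zero); ``zscore`` centers each row and
    divides by its population standard deviation (constant rows map to
    zeros).
    """
    if len(assignment.labels) != matrix.n_peaks:
        raise ParameterError("assignment does not cover all peaks")
    n_acc = assignment.n_accessons
    indicator = sp.csr_matrix(
        (np.ones(matrix.n_peaks), (np.arange(matrix.n_peaks), assignment.labels)),
        shape=(matrix.n_peaks, n_acc))
    raw = np.asarray((matrix.counts @ indicator).todense(), dtype=float)
    normalized = normalize_rows(raw, method)
    return AccessonMatrix(raw, normalized, method)


def normalize_rows(raw: np.ndarray, method: str) -> np.ndarray:
    """Per-row probability or population z-score normalization."""
    if method == "probability":
        sums = raw.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, raw / sums, 0.0)
        return out
    if method == "zscore":
        mean = raw.mean(axis=1, keepdims=True)
        sd = raw.std(axis=1, keepdims=True)  # population (n) denominator
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sd > 0, (raw - mean) / sd, 0.0)
        return out
    raise ParameterError(f"unknown normalization method: {method!r}")
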