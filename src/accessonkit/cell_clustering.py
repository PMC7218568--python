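"""Cell clustering from the normalized accesson matrix and its evaluation.

Cells are connected by a Euclidean KNN graph on their normalized accesson
rows.  The Louvain algorithm (modularity optimization) predicts the number
of communities automatically; a fixed cluster count is available through
connectivity-constrained Ward agglomeration on the same graph.  Agreement
with known labels is measured by the Adjusted Rand Index, computed from
the contingency table with exact integer arithmetic; cells whose true
label is "unknown" are excluded before evaluation.
"""

from __future__ import annotations

import logging
import random
import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import igraph as ig
import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from sklearn.neighbors import kneighbors_graph

from .accesson_core import AccessonMatrix, _constrained_ward
from .errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)

UNKNOWN = "unknown"


@dataclass
class CellGraph:
    """Symmetric KNN connectivity over cells."""

    adjacency: sp.csr_matrix
    n_neighbors: int


@dataclass
class ClusterLabels:
    """Dense per-cell cluster ids; truth labels may carry ``"unknown"``."""

    labels: np.ndarray
    n_clusters: int


def _accesson_rows(M_a: "AccessonMatrix | np.ndarray") -> np.ndarray:
    if isinstance(M_a, AccessonMatrix):
        return M_a.normalized
    return np.asarray(M_a, dtype=float)


def build_cell_graph(M_a, n_neighbors: int = 20) -> CellGraph:
    """Euclidean KNN graph of cells on normalized accesson rows (union-symmetric)."""
    X = _accesson_rows(M_a)
    n_cells = X.shape[0]
    if n_neighbors >= n_cells:
        raise ParameterError(
            f"n_neighbors={n_neighbors} must be < number of cells ({n_cells})")
    adj = kneighbors_graph(X, n_neighbors=n_neighbors,
                           mode="connectivity", include_self=False)
    adj = adj.maximum(adj.T).tocsr()
    adj.setdiag(0)
    adj.eliminate_zeros()
    return CellGraph(adj, n_neighbors)


def louvain_cluster(
    graph: CellGraph, resolution: float = 1.0, seed: int = 0
) -> ClusterLabels:
    """Louvain community detection on the cell graph.

    Deterministic for a fixed seed; communities are relabeled to dense ids
    by decreasing size.  An edgeless graph yields singleton clusters.
    """
    n_cells = graph.adjacency.shape[0]
    coo = sp.triu(graph.adjacency, k=1).tocoo()
    if coo.nnz == 0:
        warnings.warn("cell graph has no edges; every cell is a singleton")
        return ClusterLabels(np.arange(n_cells, dtype=np.int64), n_cells)
    g = ig.Graph(n=n_cells, edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    ig.set_random_number_generator(random.Random(seed))
    membership = np.asarray(
        g.community_multilevel(resolution=resolution).membership)
    ig.set_random_number_generator(random)  # restore global default
    return ClusterLabels(*_relabel_by_size(membership))


def knn_cluster(M_a, graph: CellGraph, n_clusters: int) -> ClusterLabels:
    """Fixed-count clustering: graph-constrained Ward on accesson rows."""
    X = _accesson_rows(M_a)
    n_cells = X.shape[0]
    if not 1 <= n_clusters <= n_cells:
        raise ParameterError(f"n_clusters must be in [1, {n_cells}]")
    labels = _constrained_ward(X, graph.adjacency, n_clusters)
    return ClusterLabels(*_relabel_by_size(labels))


def _relabel_by_size(labels: np.ndarray) -> tuple[np.ndarray, int]:
    ids, counts = np.unique(labels, return_counts=True)
    # decreasing size, ties by original id for determinism
    order = np.lexsort((ids, -counts))
    remap = {int(ids[o]): rank for rank, o in enumerate(order)}
    dense = np.asarray([remap[int(l)] for l in labels], dtype=np.int64)
    return dense, len(ids)


def contingency_table(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Integer contingency counts n_ij between two labelings."""
    _, ti = np.unique(truth, return_inverse=True)
    _, pi = np.unique(pred, return_inverse=True)
    table = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(table, (ti, pi), 1)
    return table


def adjusted_rand_index(
    truth, pred, ignore_unknown: bool = True, unknown_label=UNKNOWN
) -> float:
    """Adjusted Rand Index between a reference and a predicted partition.

    ARI = [sum_ij C(n_ij,2) - sum_i C(a_i,2) sum_j C(b_j,2) / C(n,2)] /
          [ (sum_i C(a_i,2) + sum_j C(b_j,2))/2
            - sum_i C(a_i,2) sum_j C(b_j,2) / C(n,2) ]

    where n_ij are contingency counts, a_i/b_j their row/column sums and n
    the total.  Cells whose truth label equals ``unknown_label`` are
    dropped first.  Binomial coefficients are evaluated in exact integer
    arithmetic.
    """
    truth = np.asarray(truth, dtype=object).ravel()
    pred = np.asarray(pred, dtype=object).ravel()
    if truth.shape != pred.shape:
        raise ValidationError("truth and pred must have equal length")
    if ignore_unknown:
        keep = truth != unknown_label
        truth, pred = truth[keep], pred[keep]
    n = truth.size
    if n < 2:
        raise ValidationError("fewer than 2 usable cells for ARI")
    table = contingency_table(truth, pred)
    sum_nij = sum(comb(int(v), 2) for v in table.ravel())
    sum_a = sum(comb(int(v), 2) for v in table.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in table.sum(axis=0))
    total = comb(n, 2)
    # exact rational arithmetic; rounding happens once, at the return
    expected = Fraction(sum_a * sum_b, total)
    maximum = Fraction(sum_a + sum_b, 2)
    if maximum == expected:  # both partitions trivial
        return 1.0
    return float((sum_nij - expected) / (maximum - expected))


def cell_correlation_matrix(M_a) -> tuple[np.ndarray, np.ndarray]:
    """Pearson cell-cell correlations with a hierarchical display order.

    Returns ``(corr, order)``: the correlation matrix in the input cell
    order, and the leaf order of average-linkage hierarchical clustering
    on 1 - correlation.  Constant rows get correlation 0 (with a warning).
    """
    X = _accesson_rows(M_a)
    if X.shape[0] < 2:
        raise ParameterError("need at least 2 cells")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("constant cell rows: their correlations are set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = (dist + dist.T) / 2
    np.fill_diagonal(dist, 0.0)
    order = leaves_list(average(squareform(np.clip(dist, 0, None), checks=False)))
    return corr, np.asarray(order)
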