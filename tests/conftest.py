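import numpy as np
import pytest
import scipy.sparse as sp

import accessonkit as ak


@pytest.fixture
def tiny_matrix() -> ak.FragmentCountMatrix:
    """4 cells x 5 peaks with hand-checkable counts."""
    counts = np.array([
        [1, 0, 3, 0, 2],
        [0, 2, 0, 0, 0],
        [4, 0, 0, 1, 0],
        [0, 0, 0, 0, 5],
    ])
    peaks = ak.PeakSet(
        chrom=np.array(["chr1", "chr1", "chr1", "chr2", "chr2"], dtype=object),
        start=np.array([1000, 5000, 9000, 1000, 7000]),
        end=np.array([1500, 5600, 9400, 1800, 7500]),
        qscore=np.array([40.0, 30.0, 36.0, 10.0, 55.0]),
    )
    barcodes = np.array([f"bc{i}" for i in range(4)], dtype=object)
    return ak.FragmentCountMatrix(sp.csr_matrix(counts), barcodes, peaks)


@pytest.fixture(scope="session")
def planted() -> tuple[ak.FragmentCountMatrix, ak.GroundTruth]:
    """Default planted dataset (3 types x 50 cells, 30 blocks x 40 peaks)."""
    return ak.generate_dataset(ak.SyntheticConfig(seed=1))


def run_pipeline_arrays(matrix, seed, n_accessons=600, norm="zscore",
                        neighbors=20, n_pcs=40, knn=10):
    """Normalize -> embed -> peak graph -> accessons -> M_a -> Louvain."""
    normalized = ak.normalize_counts(matrix)
    embedding = ak.embed_peaks(normalized, n_pcs)
    graph = ak.build_peak_graph(embedding, knn)
    assignment = ak.group_peaks(embedding, graph, n_accessons)
    M = ak.build_accesson_matrix(matrix, assignment, norm)
    cell_graph = ak.build_cell_graph(M, neighbors)
    labels = ak.louvain_cluster(cell_graph, seed=seed)
    return assignment, M, labels


@pytest.fixture(scope="session")
def planted_pipeline(planted):
    matrix, truth = planted
    assignment, M, labels = run_pipeline_arrays(matrix, seed=1)
    return matrix, truth, assignment, M, labels
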