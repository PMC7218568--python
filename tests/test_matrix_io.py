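import numpy as np
import pandas as pd
import pytest
import scipy.io
import scipy.sparse as sp

import accessonkit as ak
from accessonkit.errors import (
    ConfigurationError,
    EmptyResultError,
    FormatError,
    ValidationError,
)


def _write_triple(matrix, tmp_path, transpose=False):
    mtx = tmp_path / "m.mtx"
    bed = tmp_path / "p.bed"
    bcs = tmp_path / "b.txt"
    counts = matrix.counts.T if transpose else matrix.counts
    scipy.io.mmwrite(str(mtx), sp.coo_matrix(counts), field="integer")
    matrix.peaks.to_bed(bed)
    bcs.write_text("\n".join(matrix.barcodes) + "\n")
    return mtx, bed, bcs


class TestReadWrite:
    def test_round_trip_is_identical(self, tiny_matrix, tmp_path):
        mtx, bed, bcs = _write_triple(tiny_matrix, tmp_path)
        back = ak.read_fragment_matrix(mtx, bed, bcs)
        assert back.counts.shape == tiny_matrix.counts.shape
        assert (back.counts != tiny_matrix.counts).nnz == 0
        assert list(back.barcodes) == list(tiny_matrix.barcodes)
        np.testing.assert_array_equal(back.peaks.start, tiny_matrix.peaks.start)
        # write->read again preserves the stored (row, col, value) triples
        out = tmp_path / "o"
        out.mkdir()
        ak.write_fragment_matrix(back, out / "m.mtx", out / "p.bed", out / "b.txt")
        again = ak.read_fragment_matrix(out / "m.mtx", out / "p.bed", out / "b.txt")
        assert (again.counts != back.counts).nnz == 0

    def test_orientation_resolved_by_sidecars(self, tiny_matrix, tmp_path):
        mtx, bed, bcs = _write_triple(tiny_matrix, tmp_path, transpose=True)
        back = ak.read_fragment_matrix(mtx, bed, bcs)
        assert (back.counts != tiny_matrix.counts).nnz == 0

    def test_dimension_mismatch_raises(self, tiny_matrix, tmp_path):
        mtx, bed, bcs = _write_triple(tiny_matrix, tmp_path)
        bcs.write_text("\n".join(f"x{i}" for i in range(7)) + "\n")
        with pytest.raises(FormatError):
            ak.read_fragment_matrix(mtx, bed, bcs)

    def test_malformed_header_raises(self, tiny_matrix, tmp_path):
        mtx, bed, bcs = _write_triple(tiny_matrix, tmp_path)
        mtx.write_text("not a matrixmarket file\n1 2 3\n")
        with pytest.raises(FormatError):
            ak.read_fragment_matrix(mtx, bed, bcs)

    def test_negative_counts_rejected(self, tiny_matrix):
        bad = tiny_matrix.counts.copy().astype(np.int64)
        bad[0, 0] = -1
        with pytest.raises(ValidationError):
            ak.FragmentCountMatrix(bad, tiny_matrix.barcodes, tiny_matrix.peaks)

    def test_duplicate_barcodes_rejected(self, tiny_matrix):
        dup = tiny_matrix.barcodes.copy()
        dup[1] = dup[0]
        with pytest.raises(ValidationError):
            ak.FragmentCountMatrix(tiny_matrix.counts, dup, tiny_matrix.peaks)


class TestCellQC:
    def test_fraction_in_peaks(self, tiny_matrix):
        in_peak = tiny_matrix.row_sums().astype(float)
        totals = in_peak * np.array([1.25, 2.0, 1.0, 5.0])
        qc = ak.compute_cell_qc(tiny_matrix, totals=totals)
        np.testing.assert_allclose(qc["n_fragments"], totals)
        np.testing.assert_allclose(qc["frac_in_peaks"],
                                   [0.8, 0.5, 1.0, 0.2])

    def test_totals_absent_degenerates_to_one(self, tiny_matrix):
        qc = ak.compute_cell_qc(tiny_matrix)
        assert (qc["frac_in_peaks"] == 1.0).all()
        np.testing.assert_allclose(qc["n_fragments"], tiny_matrix.row_sums())

    def test_totals_below_row_sum_rejected(self, tiny_matrix):
        with pytest.raises(ValidationError):
            ak.compute_cell_qc(tiny_matrix, totals=np.zeros(4))

    def test_frac_tss_counts_window_intersections(self, tiny_matrix):
        # TSS at chr1:3000 with +/-2000 bp window covers [1000, 5000), which
        # intersects peak 0 (chr1:1000-1500) only
        tss = pd.DataFrame({"gene": ["g1"], "chrom": ["chr1"],
                            "tss": [3000], "strand": ["+"]})
        qc = ak.compute_cell_qc(tiny_matrix, tss_table=tss)
        in_peak = tiny_matrix.row_sums().astype(float)
        peak0 = np.asarray(tiny_matrix.counts[:, 0].todense()).ravel()
        np.testing.assert_allclose(qc["frac_tss"], peak0 / in_peak)


class TestFilters:
    def _qc(self, matrix, pf, nf):
        return pd.DataFrame({"barcode": matrix.barcodes,
                             "n_fragments": nf, "frac_in_peaks": pf})

    def test_filter_cells_strict_predicates(self, tiny_matrix):
        qc = self._qc(tiny_matrix,
                      pf=[0.25, 0.15, 0.25, 0.05],
                      nf=[3000, 3000, 1500, 500])
        kept = ak.filter_cells(tiny_matrix, qc, 0.2, 2000)
        assert list(kept.barcodes) == ["bc0"]
        assert kept.n_peaks == tiny_matrix.n_peaks

    def test_zero_cutoffs_keep_everything(self, tiny_matrix):
        qc = self._qc(tiny_matrix, pf=[1, 1, 1, 1], nf=[9, 9, 9, 9])
        kept = ak.filter_cells(tiny_matrix, qc, 0.0, 0.0)
        assert kept.n_cells == tiny_matrix.n_cells
        assert (kept.counts != tiny_matrix.counts).nnz == 0

    def test_empty_result_raises_with_counts(self, tiny_matrix):
        qc = self._qc(tiny_matrix, pf=[1, 1, 1, 1], nf=[9, 9, 9, 9])
        with pytest.raises(EmptyResultError, match="4"):
            ak.filter_cells(tiny_matrix, qc, 1.0, 10**9)

    def test_filter_peaks_threshold(self, tiny_matrix):
        # qscores [40, 30, 36, 10, 55]; >= 35 keeps peaks 0, 2, 4
        kept = ak.filter_peaks(tiny_matrix, min_qscore=35)
        np.testing.assert_array_equal(kept.peaks.qscore, [40, 36, 55])
        assert kept.n_cells == tiny_matrix.n_cells

    def test_filter_peaks_tie_break_by_file_order(self):
        peaks = ak.PeakSet(np.array(["chr1"] * 3, dtype=object),
                           np.array([0, 100, 200]), np.array([50, 150, 250]),
                           qscore=np.array([10.0, 10.0, 9.0]))
        m = ak.FragmentCountMatrix(
            sp.csr_matrix(np.ones((2, 3))), np.array(["a", "b"], dtype=object),
            peaks)
        kept = ak.filter_peaks(m, max_peaks=2)
        np.testing.assert_array_equal(kept.peaks.start, [0, 100])

    def test_filter_peaks_identity(self, tiny_matrix):
        kept = ak.filter_peaks(tiny_matrix, min_qscore=0, max_peaks=None)
        assert kept.n_peaks == tiny_matrix.n_peaks

    def test_qscore_missing_raises(self, tiny_matrix):
        stripped = ak.FragmentCountMatrix(
            tiny_matrix.counts, tiny_matrix.barcodes,
            ak.PeakSet(tiny_matrix.peaks.chrom, tiny_matrix.peaks.start,
                       tiny_matrix.peaks.end))
        with pytest.raises(ConfigurationError):
            ak.filter_peaks(stripped, min_qscore=5)

    def test_cell_and_peak_filters_commute(self, tiny_matrix):
        qc = self._qc(tiny_matrix, pf=[0.9, 0.9, 0.1, 0.9],
                      nf=[100, 100, 100, 100])
        a = ak.filter_peaks(ak.filter_cells(tiny_matrix, qc, 0.5, 10),
                            min_qscore=35)
        b = ak.filter_cells(ak.filter_peaks(tiny_matrix, min_qscore=35),
                            qc, 0.5, 10)
        assert (a.counts != b.counts).nnz == 0
        np.testing.assert_array_equal(a.peaks.start, b.peaks.start)

    def test_filtering_preserves_retained_counts(self, tiny_matrix):
        kept = ak.filter_peaks(tiny_matrix, min_qscore=35)
        orig = np.asarray(tiny_matrix.counts[:, [0, 2, 4]].todense())
        np.testing.assert_array_equal(np.asarray(kept.counts.todense()), orig)
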