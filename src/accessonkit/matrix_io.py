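"""Reading, writing, QC and filtering of sparse cell x peak fragment matrices.

The on-disk representation is the MatrixMarket coordinate format for counts,
a headerless BED-like TSV for peak intervals (``chrom  start  end  [qscore]``,
0-based half-open), and a one-barcode-per-line text file.  The in-memory
container is :class:`FragmentCountMatrix`, which always holds counts in
cells x peaks orientation regardless of how the MTX file was written.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import (
    ConfigurationError,
    EmptyResultError,
    FormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class PeakSet:
    """Genomic intervals of accessible chromatin (0-based half-open).

    Parameters
    ----------
    chrom, start, end
        Per-peak coordinates. ``start < end`` is enforced.
    qscore
        Optional -log10(Q-value) from peak calling, used for quality filtering.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    qscore: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if self.qscore is not None:
            self.qscore = np.asarray(self.qscore, dtype=float)
            if len(self.qscore) != len(self.start):
                raise ValidationError("qscore length does not match peak count")
        if not (len(self.chrom) == len(self.start) == len(self.end)):
            raise ValidationError("peak coordinate arrays have unequal lengths")
        if np.any(self.start >= self.end):
            bad = int(np.sum(self.start >= self.end))
            raise ValidationError(f"{bad} peak(s) have start >= end")

    def __len__(self) -> int:
        return len(self.start)

    def midpoints(self) -> np.ndarray:
        return (self.start + self.end) // 2

    def subset(self, indices: np.ndarray) -> "PeakSet":
        return PeakSet(
            self.chrom[indices],
            self.start[indices],
            self.end[indices],
            None if self.qscore is None else self.qscore[indices],
        )

    @classmethod
    def from_bed(cls, path: str | Path) -> "PeakSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 3:
            raise FormatError(f"{path}: expected at least 3 BED columns")
        qscore = df.iloc[:, 3].to_numpy(float) if df.shape[1] >= 4 else None
        return cls(df.iloc[:, 0].to_numpy(object),
                   df.iloc[:, 1].to_numpy(np.int64),
                   df.iloc[:, 2].to_numpy(np.int64),
                   qscore)

    def to_bed(self, path: str | Path) -> None:
        cols = {"chrom": self.chrom, "start": self.start, "end": self.end}
        if self.qscore is not None:
            cols["qscore"] = self.qscore
        pd.DataFrame(cols).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class FragmentCountMatrix:
    """Sparse non-negative integer counts, rows = cells, columns = peaks."""

    counts: sp.csr_matrix
    barcodes: np.ndarray
    peaks: PeakSet

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        n_cells, n_peaks = self.counts.shape
        if n_cells != len(self.barcodes):
            raise ValidationError(
                f"{n_cells} matrix rows but {len(self.barcodes)} barcodes")
        if n_peaks != len(self.peaks):
            raise ValidationError(
                f"{n_peaks} matrix columns but {len(self.peaks)} peaks")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValidationError("duplicate cell barcodes")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValidationError("negative counts in fragment matrix")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer counts in fragment matrix")
        self.counts.data = np.round(data).astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.counts.shape[1]

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


def read_fragment_matrix(
    mtx_path: str | Path,
    peaks_path: str | Path,
    barcodes_path: str | Path,
    orientation: str | None = None,
) -> FragmentCountMatrix:
    """Read an MTX + BED + barcode triple into cells x peaks orientation.

    Orientation is resolved by matching the MTX dimensions against the
    sidecar file lengths; a square matrix is ambiguous and requires
    ``orientation`` ("cells-by-peaks" or "peaks-by-cells") to be given.
    """
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # scipy raises ValueError on bad headers
        raise FormatError(f"{mtx_path}: cannot parse MatrixMarket file: {exc}")
    mat = sp.coo_matrix(mat)
    peaks = PeakSet.from_bed(peaks_path)
    barcodes = _read_barcodes(barcodes_path)
    n_cells, n_peaks = len(barcodes), len(peaks)

    if mat.shape == (n_cells, n_peaks) and mat.shape == (n_peaks, n_cells):
        if orientation is None:
            raise FormatError(
                "square matrix: orientation is ambiguous, pass orientation=")
        if orientation == "peaks-by-cells":
            mat = mat.T
    elif mat.shape == (n_cells, n_peaks):
        pass
    elif mat.shape == (n_peaks, n_cells):
        mat = mat.T
    else:
        raise FormatError(
            f"MTX shape {mat.shape} matches neither (cells={n_cells}, "
            f"peaks={n_peaks}) nor its transpose")
    return FragmentCountMatrix(sp.csr_matrix(mat), barcodes, peaks)


def write_fragment_matrix(
    matrix: FragmentCountMatrix,
    mtx_path: str | Path,
    peaks_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write the triple back to disk (cells x peaks orientation)."""
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(matrix.counts), field="integer")
    matrix.peaks.to_bed(peaks_path)
    Path(barcodes_path).write_text("\n".join(map(str, matrix.barcodes)) + "\n")


def _read_barcodes(path: str | Path) -> np.ndarray:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return np.asarray(lines, dtype=object)


def compute_cell_qc(
    matrix: FragmentCountMatrix,
    totals: np.ndarray | None = None,
    tss_table: pd.DataFrame | None = None,
    tss_window: int = 2000,
) -> pd.DataFrame:
    """Per-cell QC metrics: total fragments N_f and fraction in peaks P_f.

    When ``totals`` (total valid fragments per cell, from upstream alignment)
    is absent, N_f falls back to the in-peak row sum and P_f degenerates
    to 1.0.  When a TSS table (columns ``gene  chrom  tss  strand``) is
    given, ``frac_tss`` reports the fraction of in-peak counts lying in
    peaks whose interval intersects any TSS +/- ``tss_window`` bp window —
    an in-peak approximation of the read-level TSS-proximity metric.
    """
    in_peak = matrix.row_sums().astype(float)
    if totals is not None:
        totals = np.asarray(totals, dtype=float)
        if totals.shape != (matrix.n_cells,):
            raise ValidationError("totals must hold one value per barcode")
        if np.any(totals < in_peak):
            raise ValidationError(
                "per-cell totals smaller than in-peak row sums")
        n_fragments = totals
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n_fragments > 0, in_peak / n_fragments, 0.0)
    else:
        n_fragments = in_peak
        frac = np.ones(matrix.n_cells)
    qc = pd.DataFrame({
        "barcode": matrix.barcodes,
        "n_fragments": n_fragments,
        "frac_in_peaks": frac,
    })
    if tss_table is not None:
        near = _peaks_near_tss(matrix.peaks, tss_table, tss_window)
        tss_counts = np.asarray(
            matrix.counts[:, near].sum(axis=1)).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            qc["frac_tss"] = np.where(in_peak > 0, tss_counts / in_peak, 0.0)
    return qc


def _peaks_near_tss(peaks: PeakSet, tss_table: pd.DataFrame, window: int) -> np.ndarray:
    """Boolean mask over peaks intersecting any TSS +/- window (half-open)."""
    mask = np.zeros(len(peaks), dtype=bool)
    for chrom, grp in tss_table.groupby("chrom"):
        on_chrom = np.flatnonzero(peaks.chrom == chrom)
        if on_chrom.size == 0:
            continue
        starts = peaks.start[on_chrom]
        ends = peaks.end[on_chrom]
        for tss in grp["tss"].to_numpy():
            lo, hi = int(tss) - window, int(tss) + window
            mask[on_chrom[(starts < hi) & (ends > lo)]] = True
    return mask


def filter_cells(
    matrix: FragmentCountMatrix,
    qc: pd.DataFrame,
    pf_cutoff: float = 0.2,
    nf_cutoff: float = 2000,
) -> FragmentCountMatrix:
    """Retain cells with P_f > pf_cutoff and N_f > nf_cutoff (strict)."""
    qc = qc.set_index("barcode").loc[matrix.barcodes]
    keep = (qc["frac_in_peaks"].to_numpy() > pf_cutoff) & (
        qc["n_fragments"].to_numpy() > nf_cutoff)
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise EmptyResultError(
            f"no cells pass P_f > {pf_cutoff} and N_f > {nf_cutoff} "
            f"(started with {matrix.n_cells})")
    idx = np.flatnonzero(keep)
    return FragmentCountMatrix(
        matrix.counts[idx], matrix.barcodes[idx], matrix.peaks)


def filter_peaks(
    matrix: FragmentCountMatrix,
    min_qscore: float = 0.0,
    max_peaks: int | None = None,
) -> FragmentCountMatrix:
    """Quality-filter peaks by -log10(Q) and optionally cap their number.

    ``max_peaks`` keeps the top peaks by qscore with ties broken by
    original file order.  Cell rows are untouched.
    """
    qs = matrix.peaks.qscore
    if (min_qscore > 0 or max_peaks is not None) and qs is None:
        raise ConfigurationError(
            "peak qscores absent but a qscore-based filter was requested")
    keep = np.arange(matrix.n_peaks)
    if min_qscore > 0:
        keep = keep[qs[keep] >= min_qscore]
    if max_peaks is not None and keep.size > max_peaks:
        # stable sort on -qscore preserves file order among ties
        order = np.argsort(-qs[keep], kind="stable")[:max_peaks]
        keep = np.sort(keep[order])
    if keep.size == 0:
        raise EmptyResultError(
            f"no peaks pass qscore >= {min_qscore} "
            f"(started with {matrix.n_peaks})")
    if keep.size < matrix.n_peaks:
        logger.info("filter_peaks: retained %d / %d peaks",
                    keep.size, matrix.n_peaks)
    return FragmentCountMatrix(
        matrix.counts[:, keep], matrix.barcodes, matrix.peaks.subset(keep))


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of ``gene  chrom  tss  strand`` (header optional)."""
    df = pd.read_csv(path, sep="\t")
    expected = {"gene", "chrom", "tss", "strand"}
    if not expected.issubset(df.columns):
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["gene", "chrom", "tss", "strand"])
    df["tss"] = df["tss"].astype(np.int64)
    return df
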