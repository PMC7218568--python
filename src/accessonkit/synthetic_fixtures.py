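"""Synthetic sparse scATAC-seq datasets with planted structure.

The generator emits a cells x peaks Poisson count matrix in which

* cells belong to planted types, each with its own on/off profile over
  peak blocks (rates ``open_rate_high`` / ``open_rate_low``),
* peaks belong to planted co-accessible blocks: all peaks of a block
  share, in every cell, a common lognormal fluctuation factor on top of
  the type rate — the shared-fluctuation signature that defines an
  accesson and makes blocks identifiable beyond their type pattern,
* per-cell sequencing depth varies lognormally,
* an optional locus places one block's peaks inside a narrow genomic
  span, emulating a super-enhancer, and
* an optional gradient mode replaces discrete types with a latent
  pseudotime that block rates follow linearly.

Two corruption protocols mirror common robustness checks: binomial read
down-sampling and exact-count zeroing of matrix elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .accesson_core import AccessonAssignment
from .errors import ParameterError
from .matrix_io import FragmentCountMatrix, PeakSet, write_fragment_matrix

PEAK_WIDTH = 500


@dataclass
class SyntheticConfig:
    """Study conditions for the planted-structure generator."""

    n_cell_types: int = 3
    cells_per_type: int = 50
    n_peaks: int = 1200
    n_blocks: int = 30
    open_rate_high: float = 0.5
    open_rate_low: float = 0.02
    depth_scale: float = 2.0      # mean per-peak rate multiplier (library size)
    depth_sigma: float = 0.4      # lognormal sigma of per-cell depth
    block_sigma: float = 0.8      # lognormal sigma of shared block fluctuation
    peak_spacing: int = 50_000    # bp between consecutive peaks on chr1
    se_locus: tuple | None = None  # (chrom, start, n_peaks) for a planted SE
    se_span: int = 500_000
    gradient: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks > self.n_peaks:
            raise ParameterError("more blocks than peaks is infeasible")
        if self.cells_per_type < 2:
            raise ParameterError("cells_per_type must be >= 2")
        if not (0 <= self.open_rate_low <= self.open_rate_high):
            raise ParameterError("need 0 <= open_rate_low <= open_rate_high")


@dataclass
class GroundTruth:
    """Planted labels paired with a generated dataset."""

    cell_types: np.ndarray
    peak_blocks: np.ndarray
    se_interval: tuple | None = None  # (chrom, start, end, block)
    pseudotime: np.ndarray | None = None


def generate_dataset(config: SyntheticConfig) -> tuple[FragmentCountMatrix, GroundTruth]:
    """Draw a planted dataset: counts ~ Poisson(depth * type-rate * block factor)."""
    rng = np.random.default_rng(config.seed)
    n_cells = config.n_cell_types * config.cells_per_type
    n_peaks, n_blocks = config.n_peaks, config.n_blocks

    # peaks tiled along chr1; block labels round-robin so blocks are
    # genomically interleaved (accessons are genome-wide by design)
    starts = np.arange(n_peaks, dtype=np.int64) * config.peak_spacing + 1000
    chroms = np.asarray(["chr1"] * n_peaks, dtype=object)
    blocks = np.arange(n_peaks) % n_blocks
    se_interval = None
    if config.se_locus is not None:
        se_chrom, se_start, n_se = config.se_locus
        se_block = 0
        members = np.flatnonzero(blocks == se_block)[:n_se]
        locus_pos = np.sort(rng.integers(
            se_start, se_start + config.se_span - PEAK_WIDTH, size=members.size))
        starts[members] = locus_pos
        chroms[members] = se_chrom
        se_interval = (se_chrom, int(se_start),
                       int(se_start + config.se_span), se_block)
    ends = starts + PEAK_WIDTH
    peaks = PeakSet(chroms, starts, ends)

    cell_types = np.repeat(np.arange(config.n_cell_types), config.cells_per_type)
    pseudotime = None
    if config.gradient:
        pseudotime = rng.uniform(0.0, 1.0, size=n_cells)
        direction = rng.integers(0, 2, size=n_blocks)  # 1: opens along time
        w = np.where(direction[:, None] == 1,
                     pseudotime[None, :], 1.0 - pseudotime[None, :])
        block_rate = config.open_rate_low + \
            (config.open_rate_high - config.open_rate_low) * w  # blocks x cells
    else:
        pattern = _draw_patterns(rng, n_blocks, config.n_cell_types)
        rates = np.where(pattern, config.open_rate_high, config.open_rate_low)
        block_rate = rates[:, cell_types]  # blocks x cells

    depth = config.depth_scale * rng.lognormal(
        mean=0.0, sigma=config.depth_sigma, size=n_cells)
    sig = config.block_sigma
    fluct = rng.lognormal(mean=-sig * sig / 2, sigma=sig,
                          size=(n_blocks, n_cells)) if sig > 0 else \
        np.ones((n_blocks, n_cells))
    lam = (block_rate * fluct * depth[None, :])[blocks, :].T  # cells x peaks
    counts = rng.poisson(lam)
    matrix = FragmentCountMatrix(
        sp.csr_matrix(counts), _barcodes(n_cells), peaks)
    truth = GroundTruth(
        cell_types=cell_types.astype(np.int64),
        peak_blocks=blocks.astype(np.int64),
        se_interval=se_interval,
        pseudotime=pseudotime)
    return matrix, truth


def _draw_patterns(rng: np.random.Generator, n_blocks: int, n_types: int) -> np.ndarray:
    """On/off block-by-type design for well-separated planted types.

    No block is off in every type, and every pair of type profiles differs
    in at least a third of the blocks (expected half for random draws), so
    the planted types are genuinely distinct rather than near-duplicates
    produced by an unlucky draw.
    """
    min_dist = max(1, n_blocks // 3)
    while True:
        pattern = rng.integers(0, 2, size=(n_blocks, n_types)).astype(bool)
        dead = ~pattern.any(axis=1)
        pattern[dead, rng.integers(0, n_types, size=int(dead.sum()))] = True
        ok = all(
            int(np.sum(pattern[:, a] != pattern[:, b])) >= min_dist
            for a in range(n_types) for b in range(a + 1, n_types))
        if ok:
            return pattern


def _barcodes(n_cells: int) -> np.ndarray:
    width = len(str(n_cells - 1))
    return np.asarray([f"cell{str(i).zfill(width)}" for i in range(n_cells)],
                      dtype=object)


def downsample_reads(
    matrix: FragmentCountMatrix, fraction: float, seed: int = 0
) -> FragmentCountMatrix:
    """Thin every count binomially: count -> Binomial(count, fraction).

    Each read carries an independent seed-determined uniform and is kept
    iff it falls below ``fraction``, so for a fixed seed the reads
    retained at a lower fraction are a subset of those retained at a
    higher one — successive points of a retention curve are nested, which
    removes spurious non-monotonicity from paired comparisons.  The
    marginal law of every entry is still Binomial(count, fraction).
    """
    if not 0 <= fraction <= 1:
        raise ParameterError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = matrix.counts.copy()
    counts = out.data
    total_reads = int(counts.sum())
    u = rng.random(total_reads)
    entry_of_read = np.repeat(np.arange(counts.size), counts)
    kept = np.bincount(entry_of_read[u < fraction], minlength=counts.size)
    out.data = kept.astype(np.int64)
    out.eliminate_zeros()
    return FragmentCountMatrix(out, matrix.barcodes, matrix.peaks)


def inject_noise(
    matrix: FragmentCountMatrix, fraction: float, seed: int = 0
) -> FragmentCountMatrix:
    """Zero exactly round(fraction * nnz) uniformly chosen nonzero entries.

    The entries are the first round(fraction * nnz) elements of one
    seed-determined permutation of the nonzeros, so for a fixed seed the
    zeroed set at a lower fraction is contained in the zeroed set at a
    higher one (nested corruption levels); any prefix of a uniform random
    permutation is still a uniform random subset.
    """
    if not 0 <= fraction <= 1:
        raise ParameterError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = matrix.counts.copy()
    nnz = out.nnz
    n_zero = int(round(fraction * nnz))
    if n_zero:
        hit = rng.permutation(nnz)[:n_zero]
        out.data[hit] = 0
        out.eliminate_zeros()
    return FragmentCountMatrix(out, matrix.barcodes, matrix.peaks)


def se_peak_fixture(
    n_background: int = 2000,
    n_accessons: int = 600,
    n_locus_peaks: int = 20,
    locus_span: int = 500_000,
    chrom_length: int = 100_000_000,
    plant: bool = True,
    seed: int = 0,
) -> tuple[PeakSet, AccessonAssignment, tuple | None]:
    """Peak set + accesson labels for super-enhancer benchmarking.

    Background peaks are spread along one chromosome with uniformly
    jittered spacing and uniformly shuffled accesson labels.  With
    ``plant``, an extra single-accesson locus of ``n_locus_peaks`` peaks
    is placed inside a ``locus_span`` window mid-chromosome.  Labels are
    re-factorized to dense ids; the planted accesson's id is returned
    with the locus interval.
    """
    rng = np.random.default_rng(seed)
    spacing = chrom_length // n_background
    pos = np.arange(n_background) * spacing + rng.integers(
        0, max(1, spacing - PEAK_WIDTH), size=n_background)
    labels = rng.integers(0, n_accessons, size=n_background)
    locus = None
    if plant:
        locus_start = chrom_length // 2
        locus_pos = np.sort(rng.integers(
            locus_start, locus_start + locus_span - PEAK_WIDTH,
            size=n_locus_peaks))
        pos = np.concatenate([pos, locus_pos])
        labels = np.concatenate(
            [labels, np.full(n_locus_peaks, n_accessons, dtype=np.int64)])
        locus = (locus_start, locus_start + locus_span)
    order = np.argsort(pos, kind="stable")
    pos, labels = pos[order], labels[order]
    dense, uniques = pd.factorize(labels, sort=True)
    peaks = PeakSet(np.asarray(["chr1"] * pos.size, dtype=object),
                    pos, pos + PEAK_WIDTH)
    assignment = AccessonAssignment(dense, len(uniques))
    if plant:
        planted_id = int(np.flatnonzero(uniques == n_accessons)[0])
        locus = ("chr1", locus[0], locus[1], planted_id)
    return peaks, assignment, locus


def write_dataset(
    matrix: FragmentCountMatrix, truth: GroundTruth, outdir: str | Path
) -> dict[str, str]:
    """Write the standard file triple plus ground-truth tables; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": str(outdir / "counts.mtx"),
        "peaks": str(outdir / "peaks.bed"),
        "barcodes": str(outdir / "barcodes.txt"),
        "cell_types": str(outdir / "cell_types.tsv"),
        "peak_blocks": str(outdir / "peak_blocks.tsv"),
    }
    write_fragment_matrix(matrix, paths["mtx"], paths["peaks"], paths["barcodes"])
    pd.DataFrame({"barcode": matrix.barcodes,
                  "cell_type": truth.cell_types}).to_csv(
        paths["cell_types"], sep="\t", index=False)
    pd.DataFrame({"peak_index": np.arange(matrix.n_peaks),
                  "block": truth.peak_blocks}).to_csv(
        paths["peak_blocks"], sep="\t", index=False)
    if truth.pseudotime is not None:
        paths["pseudotime"] = str(outdir / "pseudotime.tsv")
        pd.DataFrame({"barcode": matrix.barcodes,
                      "pseudotime": truth.pseudotime}).to_csv(
            paths["pseudotime"], sep="\t", index=False)
    return paths
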