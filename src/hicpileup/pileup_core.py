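"""Window extraction, rescaling and accumulation into a mean pile-up.

The accumulator keeps a running per-pixel sum of finite values and a
per-pixel count of finite contributions, so the final mean is robust to
missing pixels from invalid (unmappable) bins: a pixel's mean is its sum
divided by its own contribution count, not by the total window tally. When
no bin is invalid the two denominators coincide.

Rescaling uses area-weighted block (conservative) resampling: it preserves
total intensity for constant inputs, maps a block matrix onto its block
averages, and is reproducible across platforms. Missing input pixels are
imputed by the window's per-diagonal mean before resampling and output
pixels drawing more than half their weight from missing inputs are re-masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .contact_io import ContactMatrix
from .pairing import NoUsableWindowsError, WindowSpec

__all__ = [
    "PileupAccumulator",
    "Pileup",
    "extract_window",
    "rescale_window",
    "accumulate",
    "merge_accumulators",
    "pileup_windows",
    "finalize_mean",
]


@dataclass
class Pileup:
    """A finalized pile-up: per-pixel mean matrix plus provenance metadata."""

    matrix: np.ndarray
    n_windows: int
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.matrix.shape


class PileupAccumulator:
    """Running sums for a pile-up of fixed window shape.

    Parameters
    ----------
    size : int
        Window side length (``2*flank + 1``, or the rescale target size).
    coverage : bool
        Record per-bin chromosome coverage across the window flanks, needed
        later for coverage normalization.
    rescaled : bool
        Windows arrive pre-rescaled to ``size``.
    """

    def __init__(self, size: int, coverage: bool = False, rescaled: bool = False):
        self.size = int(size)
        self.sum_matrix = np.zeros((size, size))
        self.count_matrix = np.zeros((size, size), dtype=np.int64)
        self.n_windows = 0
        self.coverage = coverage
        self.rescaled = rescaled
        self.cov_row = np.zeros(size) if coverage else None
        self.cov_col = np.zeros(size) if coverage else None

    def copy(self) -> "PileupAccumulator":
        acc = PileupAccumulator(self.size, self.coverage, self.rescaled)
        acc.sum_matrix = self.sum_matrix.copy()
        acc.count_matrix = self.count_matrix.copy()
        acc.n_windows = self.n_windows
        if self.coverage:
            acc.cov_row = self.cov_row.copy()
            acc.cov_col = self.cov_col.copy()
        return acc


def extract_window(
    matrix: ContactMatrix, spec: WindowSpec, balanced: bool = False
) -> np.ndarray:
    """Dense window of the contact map for one spec.

    Unstored pixels between valid bins are zero; in balanced mode pixels
    touching an invalid-weight bin are NaN. On-diagonal windows reflect the
    upper-triangular store symmetrically. Anchored specs flagged
    ``transpose`` are transposed so the anchor lands on the row axis.
    """
    n = matrix.genome.n_bins(spec.chrom)
    assert spec.in_range(n), "window spec out of chromosome range"
    r0, r1 = spec.row_range
    c0, c1 = spec.col_range
    sym = matrix.symmetric(spec.chrom)
    win = sym[r0:r1, c0:c1].toarray()
    if balanced:
        w = matrix.chrom_weights(spec.chrom)
        win = win * np.outer(w[r0:r1], w[c0:c1])
    if spec.transpose:
        win = win.T.copy()
    return win


def _agg_weights(n_in: int, n_out: int) -> np.ndarray:
    """Row-aggregation matrix W (n_out x n_in): area overlap, rows sum to 1."""
    edges = np.linspace(0.0, n_in, n_out + 1)
    w = np.zeros((n_out, n_in))
    for a in range(n_out):
        lo, hi = edges[a], edges[a + 1]
        i0 = int(np.floor(lo))
        i1 = min(int(np.ceil(hi)), n_in)
        for i in range(i0, i1):
            w[a, i] = min(hi, i + 1.0) - max(lo, float(i))
    w /= w.sum(axis=1, keepdims=True)
    return w


def _diagonal_mean_impute(win: np.ndarray) -> np.ndarray:
    """Fill NaNs with the mean of their (constant-separation) diagonal."""
    out = win.copy()
    nr, nc = win.shape
    rows, cols = np.indices(win.shape)
    offs = cols - rows
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        overall = np.nanmean(win) if np.isfinite(win).any() else 0.0
    for k in range(-(nr - 1), nc):
        mask = offs == k
        vals = win[mask]
        finite = np.isfinite(vals)
        fill = vals[finite].mean() if finite.any() else overall
        bad = mask & ~np.isfinite(win)
        out[bad] = fill
    return out


def rescale_window(window: np.ndarray, target_size_bins: int) -> np.ndarray:
    """Resample a window to ``target_size_bins`` square, conservatively.

    Output pixels taking more than 50% of their area weight from missing
    (NaN) input pixels are NaN in the result.
    """
    t = int(target_size_bins)
    if t < 3 or t % 2 == 0:
        raise ValueError("target size must be odd and >= 3")
    win = np.asarray(window, dtype=float)
    missing = ~np.isfinite(win)
    wr = _agg_weights(win.shape[0], t)
    wc = _agg_weights(win.shape[1], t)
    filled = _diagonal_mean_impute(win) if missing.any() else win
    out = wr @ filled @ wc.T
    if missing.any():
        frac = wr @ missing.astype(float) @ wc.T
        out[frac > 0.5] = np.nan
    return out


def rescale_vector(vec: np.ndarray, target_size_bins: int) -> np.ndarray:
    """Resample a 1D coverage profile alongside its window."""
    w = _agg_weights(len(vec), int(target_size_bins))
    return w @ np.asarray(vec, dtype=float)


def accumulate(
    acc: PileupAccumulator,
    window: np.ndarray,
    spec: WindowSpec | None = None,
    chrom_coverage: np.ndarray | None = None,
) -> PileupAccumulator:
    """Add one (already extracted and, if needed, rescaled) window in place."""
    if window.shape != (acc.size, acc.size):
        raise ValueError(
            f"window shape {window.shape} does not match accumulator "
            f"({acc.size}, {acc.size})"
        )
    finite = np.isfinite(window)
    acc.sum_matrix[finite] += window[finite]
    acc.count_matrix += finite
    acc.n_windows += 1
    if acc.coverage:
        if chrom_coverage is None:
            raise ValueError("coverage recording enabled but no coverage given")
        r0, r1 = spec.row_range
        c0, c1 = spec.col_range
        cov_r = np.asarray(chrom_coverage[r0:r1], dtype=float)
        cov_c = np.asarray(chrom_coverage[c0:c1], dtype=float)
        if spec.transpose:
            cov_r, cov_c = cov_c, cov_r
        if acc.rescaled:
            cov_r = rescale_vector(cov_r, acc.size)
            cov_c = rescale_vector(cov_c, acc.size)
        acc.cov_row += cov_r
        acc.cov_col += cov_c
    return acc


def merge_accumulators(accs) -> PileupAccumulator:
    """Field-wise sum of per-chromosome accumulators (parallel merge)."""
    accs = list(accs)
    if not accs:
        raise ValueError("nothing to merge")
    first = accs[0]
    for other in accs[1:]:
        if other.size != first.size:
            raise ValueError("cannot merge accumulators of different shapes")
        if other.coverage != first.coverage or other.rescaled != first.rescaled:
            raise ValueError("cannot merge accumulators with different modes")
    out = first.copy()
    for other in accs[1:]:
        out.sum_matrix += other.sum_matrix
        out.count_matrix += other.count_matrix
        out.n_windows += other.n_windows
        if out.coverage:
            out.cov_row += other.cov_row
            out.cov_col += other.cov_col
    return out


def pileup_windows(
    matrix: ContactMatrix,
    specs,
    balanced: bool = False,
    coverage: bool = False,
    rescale_target: int | None = None,
) -> PileupAccumulator:
    """Extract, optionally rescale, and accumulate a whole window stream.

    The workhorse shared by observed pile-ups and shifted-control pile-ups,
    so numerator and denominator always follow identical rules.
    """
    specs = list(specs)
    if not specs:
        raise NoUsableWindowsError("empty window stream")
    if rescale_target is not None:
        size = int(rescale_target)
    else:
        size = 2 * specs[0].flank + 1
    acc = PileupAccumulator(size, coverage=coverage, rescaled=rescale_target is not None)
    cov_cache: dict = {}
    for spec in specs:
        win = extract_window(matrix, spec, balanced=balanced)
        if rescale_target is not None:
            win = rescale_window(win, size)
        cov = None
        if coverage:
            if spec.chrom not in cov_cache:
                cov_cache[spec.chrom] = matrix.coverage(spec.chrom)
            cov = cov_cache[spec.chrom]
        accumulate(acc, win, spec, cov)
    return acc


def finalize_mean(acc: PileupAccumulator, metadata: dict | None = None) -> Pileup:
    """Per-pixel mean over finite contributions; zero-count pixels are NaN."""
    if acc.n_windows == 0:
        raise NoUsableWindowsError("no usable windows were accumulated")
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.where(
            acc.count_matrix > 0, acc.sum_matrix / acc.count_matrix, np.nan
        )
    meta = dict(metadata or {})
    meta.setdefault("rescaled", acc.rescaled)
    return Pileup(mat, acc.n_windows, meta)
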