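"""Distance and bias normalization of pile-ups.

Four strategies:

* **expected** — under the distance-only null, the whole-chromosome expected
  map is diagonal-constant (Toeplitz): ``A[i, j] = A[i+1, j+1] = d[|i-j|]``
  where ``d`` is the mean contact per diagonal. An expected window for any
  spec is built directly from ``d`` in O(window^2) memory, never from the
  full matrix. Expected windows over the same spec stream as the observed
  pile-up are averaged into a normalizing matrix (ratio of averages, never
  average of ratios).
* **shifted controls** — when no expected profile is trustworthy (e.g.
  single-cell data), the whole pile-up procedure is repeated on randomly
  shifted copies of each window that keep the anchor separation; the control
  pile-up becomes the normalizing matrix. Controls inherit every active
  option (balancing, coverage normalization, rescaling).
* **coverage** — for unbalanced data, the pile-up is divided by the outer
  product of the mean flank coverage profiles (each scaled to unit mean),
  mitigating per-bin visibility bias.
* **none** — raw averaged windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .contact_io import ContactMatrix, ExpectedProfile
from .pairing import WindowSpec
from .pileup_core import (
    Pileup,
    PileupAccumulator,
    accumulate,
    finalize_mean,
    pileup_windows,
    rescale_window,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizerMatrix",
    "compute_expected",
    "expected_window",
    "expected_normalizer",
    "shifted_controls",
    "control_normalizer",
    "coverage_normalize",
    "apply_normalizer",
]


@dataclass
class NormalizerMatrix:
    """A matrix to divide a pile-up by, with provenance."""

    matrix: np.ndarray
    provenance: str  # expected | shifted_controls | none
    n_control_windows: int = 0


def compute_expected(
    matrix: ContactMatrix, balanced: bool = True, chroms=None
) -> ExpectedProfile:
    """Mean contact value at each diagonal, per chromosome.

    The mean runs over all valid bin pairs at each offset, including
    structural zeros between valid bins (expected is a mean over the map,
    not over stored pixels). In balanced mode pairs touching an
    invalid-weight bin are excluded. ``chroms`` restricts the computation to
    a subset of chromosomes.
    """
    profiles = {}
    for chrom in chroms or matrix.genome.chrom_names:
        n = matrix.genome.n_bins(chrom)
        upper = matrix.upper(chrom).tocoo()
        rows, cols, vals = upper.row, upper.col, upper.data.astype(float)
        if balanced:
            w = matrix.chrom_weights(chrom)
            vals = vals * w[rows] * w[cols]
            valid = np.isfinite(w).astype(float)
        else:
            valid = np.ones(n)
        if valid.sum() < 2:
            logger.warning("%s: fewer than 2 valid bins; expected is all-missing", chrom)
            profiles[chrom] = np.full(n, np.nan)
            continue
        keep = np.isfinite(vals)
        offs = cols[keep] - rows[keep]
        sums = np.bincount(offs, weights=vals[keep], minlength=n)
        # number of valid (i, i+k) pairs at offset k: autocorrelation of the
        # valid-bin indicator
        counts = np.correlate(valid, valid, mode="full")[n - 1 :]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(counts > 0.5, sums / counts, np.nan)
        profiles[chrom] = d
    return ExpectedProfile(profiles, value_column="computed")


def expected_window(profile: ExpectedProfile, spec: WindowSpec) -> np.ndarray:
    """Toeplitz expected window: ``E[a, b] = d[|row_bin(a) - col_bin(b)|]``.

    Allocates only the window footprint; the full expected matrix of the
    chromosome is never materialized.
    """
    d = profile.d(spec.chrom)
    r0, r1 = spec.row_range
    c0, c1 = spec.col_range
    offs = np.abs(np.subtract.outer(np.arange(r0, r1), np.arange(c0, c1)))
    win = d[offs]
    # |offset| makes the window symmetric to transposition of anchored specs
    return win


def expected_normalizer(
    profile: ExpectedProfile,
    specs,
    rescale_target: int | None = None,
) -> NormalizerMatrix:
    """Element-wise mean of expected windows over the same spec stream.

    Ratio of averages: the observed pile-up is later divided by this mean,
    matching the order of operations of the pile-up procedure itself.
    """
    specs = list(specs)
    if rescale_target is not None:
        size = int(rescale_target)
    else:
        size = 2 * specs[0].flank + 1
    acc = PileupAccumulator(size, rescaled=rescale_target is not None)
    for spec in specs:
        win = expected_window(profile, spec)
        if rescale_target is not None:
            win = rescale_window(win, size)
        accumulate(acc, win, spec)
    pu = finalize_mean(acc)
    return NormalizerMatrix(pu.matrix, "expected", 0)


def _shift_bounds(spec: WindowSpec, n_bins: int) -> tuple:
    """Inclusive offset range keeping the shifted window inside the chromosome."""
    r0, _ = spec.row_range
    _, c1 = spec.col_range
    return -r0, n_bins - c1


def _default_min_shift(spec: WindowSpec) -> int:
    if spec.is_rescaled:
        width = spec.span_i[1] - spec.span_i[0]
        return max((width - 1) // 2, 1)
    return max(spec.flank, 1)


def shifted_controls(
    spec: WindowSpec,
    n_shifts: int,
    genome,
    rng: np.random.Generator,
    min_shift_bins: int | None = None,
):
    """Randomly shifted control specs matched to one source window.

    Each control moves both anchors by one shared offset, preserving the
    separation; offsets are drawn uniformly from the in-chromosome positions
    at least ``min_shift_bins`` (default: the flank) away from the source.
    A chromosome too short to place any control yields an empty list.
    """
    if n_shifts < 1:
        raise ValueError("n_shifts must be >= 1")
    n_bins = genome.n_bins(spec.chrom)
    min_shift = _default_min_shift(spec) if min_shift_bins is None else min_shift_bins
    t_min, t_max = _shift_bounds(spec, n_bins)
    n_neg = max(0, min(-min_shift, t_max) - t_min + 1)
    n_pos = max(0, t_max - max(min_shift, t_min) + 1)
    total = n_neg + n_pos
    if total == 0:
        return []
    out = []
    for _ in range(n_shifts):
        u = int(rng.integers(total))
        t = (t_min + u) if u < n_neg else (max(min_shift, t_min) + (u - n_neg))
        if spec.is_rescaled:
            si = (spec.span_i[0] + t, spec.span_i[1] + t)
            sj = (spec.span_j[0] + t, spec.span_j[1] + t)
            ctrl = WindowSpec(
                spec.chrom,
                spec.bin_i + t,
                spec.bin_j + t,
                span_i=si,
                span_j=sj,
                kind="control",
                source_ids=spec.source_ids,
                transpose=spec.transpose,
            )
        else:
            ctrl = WindowSpec(
                spec.chrom,
                spec.bin_i + t,
                spec.bin_j + t,
                flank=spec.flank,
                kind="control",
                source_ids=spec.source_ids,
                transpose=spec.transpose,
            )
        out.append(ctrl)
    return out


def control_specs_for_stream(
    specs,
    n_shifts: int,
    genome,
    rng: np.random.Generator,
    min_shift_bins: int | None = None,
) -> list:
    """Shifted controls for every spec in a stream; skipped specs counted."""
    controls, skipped = [], 0
    for spec in specs:
        ctrl = shifted_controls(spec, n_shifts, genome, rng, min_shift_bins)
        if not ctrl:
            skipped += 1
        controls.extend(ctrl)
    if skipped:
        logger.info("%d window(s) contributed no shifted controls", skipped)
    return controls


def control_normalizer(
    matrix: ContactMatrix,
    control_specs,
    balanced: bool = False,
    coverage: bool = False,
    rescale_target: int | None = None,
) -> NormalizerMatrix:
    """Full pile-up over control windows, with the same rules as the observed."""
    acc = pileup_windows(
        matrix,
        control_specs,
        balanced=balanced,
        coverage=coverage,
        rescale_target=rescale_target,
    )
    if coverage:
        acc = coverage_normalize(acc)
    pu = finalize_mean(acc)
    return NormalizerMatrix(pu.matrix, "shifted_controls", acc.n_windows)


def coverage_normalize(acc: PileupAccumulator) -> PileupAccumulator:
    """Divide a pile-up by the outer product of its flank coverage profiles.

    Each mean coverage profile is scaled to unit mean first, so uniform
    coverage is a no-op. Pixels under a zero-coverage bin become missing.
    Intended for unbalanced data; with balanced data the bias is already
    removed and this normalization is redundant.
    """
    if not acc.coverage:
        raise ValueError("coverage recording was not enabled on this accumulator")
    out = acc.copy()
    prof_r = acc.cov_row / max(acc.n_windows, 1)
    prof_c = acc.cov_col / max(acc.n_windows, 1)
    mr, mc = prof_r.mean(), prof_c.mean()
    if mr <= 0 or mc <= 0:
        raise ValueError("coverage profiles are degenerate (non-positive mean)")
    prof_r = prof_r / mr
    prof_c = prof_c / mc
    denom = np.outer(prof_r, prof_c)
    zero = denom <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out.sum_matrix = np.where(zero, 0.0, acc.sum_matrix / np.where(zero, 1.0, denom))
    out.count_matrix = np.where(zero, 0, acc.count_matrix)
    return out


def apply_normalizer(pileup: Pileup, normalizer: NormalizerMatrix) -> Pileup:
    """Element-wise ratio of a pile-up to its normalizing matrix.

    Pixels missing in either operand, and pixels whose normalizer is zero,
    are missing in the result (with a warning).
    """
    norm = normalizer.matrix
    if norm.shape != pileup.matrix.shape:
        raise ValueError("normalizer shape does not match pile-up")
    bad = ~np.isfinite(norm) | (norm == 0)
    n_zero = int((norm == 0).sum())
    if n_zero:
        warnings.warn(
            f"normalizer has {n_zero} zero pixel(s); output pixels set missing",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.where(bad, np.nan, pileup.matrix / np.where(bad, 1.0, norm))
    meta = dict(pileup.metadata)
    meta["normalization"] = normalizer.provenance
    if normalizer.n_control_windows:
        meta["n_control_windows"] = normalizer.n_control_windows
    return Pileup(mat, pileup.n_windows, meta)
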