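"""Scores and quality control for finalized pile-ups.

Dataset-level enrichment is the mean of the central 3x3 pixel square of the
pile-up. Noisy pile-ups (relevant for single-cell data) are flagged by the
coefficient of variation of their 5x5 upper-left and lower-right corners:
a CV of 0.5 or above in either corner fails the filter. For display, a
pile-up can be normalized to the average of its top-left and bottom-right
corner pixels to put panels on the same scale.

Per-region "loop-ability" scores one anchor region against all its partners:
the central pixel (a single pixel, not the 3x3 mean) of the anchored pile-up
retains locus-specific information that whole-set averages lose.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact_io import ContactMatrix, ExpectedProfile, RegionSet
from .pairing import anchored_pairs
from .normalization import (
    apply_normalizer,
    compute_expected,
    control_normalizer,
    control_specs_for_stream,
    coverage_normalize,
    expected_normalizer,
)
from .pileup_core import Pileup, finalize_mean, pileup_windows

logger = logging.getLogger(__name__)

__all__ = [
    "PileupScore",
    "central_enrichment",
    "central_pixel",
    "corner_normalize",
    "corner_cv",
    "cv_filter",
    "score_pileup",
    "loopability_table",
]

CV_CORNER_SIZE = 5
CV_THRESHOLD = 0.5


def _matrix(pileup) -> np.ndarray:
    return pileup.matrix if isinstance(pileup, Pileup) else np.asarray(pileup, float)


@dataclass
class PileupScore:
    central3x3: float
    corner_mean_tl_br: float
    lower_left_mean: float
    cv_tl: float
    cv_br: float
    passed_cv: bool

    @property
    def corner_cv_max(self) -> float:
        return max(self.cv_tl, self.cv_br)


def central_enrichment(pileup) -> float:
    """Mean of the central 3x3 pixels, missing-aware.

    For a degenerate 3x3 pile-up this is the mean of the whole matrix;
    returns NaN if all nine pixels are missing.
    """
    mat = _matrix(pileup)
    n = mat.shape[0]
    if n < 3 or n % 2 == 0:
        raise ValueError("pile-up must be odd-sized and >= 3x3")
    c = n // 2
    block = mat[c - 1 : c + 2, c - 1 : c + 2]
    if not np.isfinite(block).any():
        return float("nan")
    return float(np.nanmean(block))


def central_pixel(pileup) -> float:
    """Value of the single central pixel (the loop-ability statistic)."""
    mat = _matrix(pileup)
    c = mat.shape[0] // 2
    return float(mat[c, c])


def _corner_blocks(mat: np.ndarray, size: int):
    return mat[:size, :size], mat[-size:, -size:]


def corner_normalize(pileup, corner_size: int = 1) -> Pileup:
    """Divide by the mean of the top-left and bottom-right corner blocks.

    Default corner size is a single pixel. Scale-invariant display
    normalization; idempotent.
    """
    mat = _matrix(pileup)
    tl, br = _corner_blocks(mat, corner_size)
    both = np.concatenate([tl.ravel(), br.ravel()])
    if not np.isfinite(both).any() or np.nanmean(both) <= 0:
        raise ValueError("cannot corner-normalize: corner mean missing or <= 0")
    scale = float(np.nanmean(both))
    if isinstance(pileup, Pileup):
        meta = dict(pileup.metadata)
        meta["corner_normalized"] = True
        return Pileup(mat / scale, pileup.n_windows, meta)
    return Pileup(mat / scale, 0, {"corner_normalized": True})


def lower_left_mean(pileup, corner_size: int = 1) -> float:
    """Mean of the lower-left corner block (off-diagonal short-range side)."""
    mat = _matrix(pileup)
    block = mat[-corner_size:, :corner_size]
    return float(np.nanmean(block)) if np.isfinite(block).any() else float("nan")


def corner_cv(pileup, corner_size: int = CV_CORNER_SIZE) -> tuple:
    """Coefficient of variation (sample std / mean) of the two noise corners.

    Requires the pile-up to be large enough that the corners cannot touch
    the central 3x3 square (>= 13x13 for 5x5 corners). A corner with more
    than half its pixels missing has undefined (NaN) CV.
    """
    mat = _matrix(pileup)
    n = mat.shape[0]
    if n < 2 * corner_size + 3:
        raise ValueError(
            f"pile-up of size {n} too small for {corner_size}x{corner_size} "
            f"corners clear of the central 3x3 (need >= {2 * corner_size + 3})"
        )
    out = []
    for block in _corner_blocks(mat, corner_size):
        vals = block.ravel()
        finite = np.isfinite(vals)
        if finite.sum() <= vals.size / 2 or finite.sum() < 2:
            out.append(float("nan"))
            continue
        v = vals[finite]
        m = v.mean()
        out.append(float(v.std(ddof=1) / m) if m != 0 else float("inf"))
    return tuple(out)


def cv_filter(pileup, threshold: float = CV_THRESHOLD) -> bool:
    """True if the pile-up passes the corner-noise filter.

    Fails when either corner CV is ``threshold`` or above (boundary
    inclusive), or when a CV is undefined (conservative).
    """
    cv_tl, cv_br = corner_cv(pileup)
    if math.isnan(cv_tl) or math.isnan(cv_br):
        return False
    return bool(max(cv_tl, cv_br) < threshold)


def score_pileup(pileup, cv_threshold: float = CV_THRESHOLD) -> PileupScore:
    """All standard scores of one pile-up in one pass."""
    mat = _matrix(pileup)
    tl, br = _corner_blocks(mat, 1)
    corner_mean = float(np.nanmean(np.concatenate([tl.ravel(), br.ravel()])))
    if mat.shape[0] >= 2 * CV_CORNER_SIZE + 3:
        cv_tl, cv_br = corner_cv(pileup)
        passed = (
            not (math.isnan(cv_tl) or math.isnan(cv_br))
            and max(cv_tl, cv_br) < cv_threshold
        )
    else:
        cv_tl = cv_br = float("nan")
        passed = True  # too small to assess corner noise
    return PileupScore(
        central3x3=central_enrichment(pileup),
        corner_mean_tl_br=corner_mean,
        lower_left_mean=lower_left_mean(pileup),
        cv_tl=cv_tl,
        cv_br=cv_br,
        passed_cv=passed,
    )


def loopability_table(
    regions: RegionSet,
    matrix: ContactMatrix,
    flank_bp: int,
    min_sep: float = 0,
    max_sep: float = math.inf,
    expected: ExpectedProfile | None = None,
    nshifts: int | None = None,
    balanced: bool = True,
    coverage: bool = False,
    seed: int = 0,
    use_central_3x3: bool = False,
    cv_threshold: float = CV_THRESHOLD,
) -> pd.DataFrame:
    """Per-region loop-ability: each region piled against all its partners.

    One row per region: id, coordinates, number of partner windows, central
    score (single central pixel by default; 3x3 mean with
    ``use_central_3x3``), corner CVs and the CV-filter flag. Regions with no
    in-band partners get a missing score, not an error; regions failing the
    CV filter are flagged, never silently dropped.
    """
    if (expected is None) == (nshifts is None):
        raise ValueError("specify exactly one of expected= or nshifts=")
    if expected is None and nshifts is not None and nshifts < 1:
        raise ValueError("nshifts must be >= 1")
    score_fn = central_enrichment if use_central_3x3 else central_pixel
    rows = []
    for idx, rec in zip(regions.table.index, regions.table.itertuples()):
        base = dict(
            region=rec.name,
            chrom=rec.chrom,
            start=rec.start,
            end=rec.end,
        )
        windows = anchored_pairs(idx, regions, flank_bp, min_sep, max_sep)
        if not windows:
            rows.append(
                {**base, "n_windows": 0, "score": np.nan, "cv_tl": np.nan,
                 "cv_br": np.nan, "pass": False}
            )
            continue
        acc = pileup_windows(matrix, windows, balanced=balanced, coverage=coverage)
        if coverage:
            acc = coverage_normalize(acc)
        pu = finalize_mean(acc)
        if expected is not None:
            norm = expected_normalizer(expected, windows)
        else:
            rng = np.random.default_rng(np.random.SeedSequence([seed, idx]))
            ctrl = control_specs_for_stream(windows, nshifts, matrix.genome, rng)
            norm = control_normalizer(
                matrix, ctrl, balanced=balanced, coverage=coverage
            )
        pu = apply_normalizer(pu, norm)
        if pu.matrix.shape[0] >= 2 * CV_CORNER_SIZE + 3:
            cv_tl, cv_br = corner_cv(pu)
            passed = (
                not (math.isnan(cv_tl) or math.isnan(cv_br))
                and max(cv_tl, cv_br) < cv_threshold
            )
        else:
            cv_tl = cv_br = np.nan
            passed = True
        rows.append(
            {**base, "n_windows": len(windows), "score": score_fn(pu),
             "cv_tl": cv_tl, "cv_br": cv_br, "pass": passed}
        )
    return pd.DataFrame(rows)
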