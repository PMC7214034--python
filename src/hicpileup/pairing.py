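"""Turn region and pair annotations into explicit 2D windows to average.

Every pile-up variant reduces to a stream of :class:`WindowSpec` objects:
off-diagonal pairs (loop anchors), all pairwise combinations of one region
set, cross pairs between two sets, on-diagonal local windows, variable-span
rescaled windows and anchored (loop-ability) windows.

Edge policy: a window that would cross a chromosome end is dropped entirely
rather than padded, which keeps per-pixel window counts equal across the
pile-up; drop counts are tallied by reason. Separation filters are inclusive
bounds on center-to-center distance in base pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .contact_io import BinnedGenome, PairSet, RegionSet

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "WindowList",
    "NoUsableWindowsError",
    "pairs_from_bedpe",
    "combinations_from_regions",
    "cross_pairs",
    "local_windows",
    "rescaled_windows",
    "anchored_pairs",
    "subset_sample",
    "flank_bins",
]


class NoUsableWindowsError(ValueError):
    """Every candidate window was dropped; message lists counts per reason."""


@dataclass(frozen=True)
class WindowSpec:
    """One 2D region of the contact map to extract.

    Fixed-flank mode: the window is
    ``[bin_i - flank, bin_i + flank] x [bin_j - flank, bin_j + flank]``
    (``bin_i == bin_j`` for local windows). Rescale mode: ``span_i`` and
    ``span_j`` are half-open bin ranges of variable size. ``transpose`` flags
    anchored windows whose anchor lies downstream, so the anchor always ends
    up on the row axis after extraction.
    """

    chrom: str
    bin_i: int
    bin_j: int
    flank: int = 0
    span_i: tuple | None = None
    span_j: tuple | None = None
    kind: str = "pair"  # pair | local | rescaled | control
    source_ids: tuple = ()
    transpose: bool = False

    @property
    def is_rescaled(self) -> bool:
        return self.span_i is not None

    @property
    def row_range(self) -> tuple:
        if self.is_rescaled:
            return self.span_i
        return (self.bin_i - self.flank, self.bin_i + self.flank + 1)

    @property
    def col_range(self) -> tuple:
        if self.is_rescaled:
            return self.span_j
        return (self.bin_j - self.flank, self.bin_j + self.flank + 1)

    @property
    def separation_bins(self) -> int:
        return self.bin_j - self.bin_i

    def shape(self) -> tuple:
        r, c = self.row_range, self.col_range
        return (r[1] - r[0], c[1] - c[0])

    def in_range(self, n_bins: int) -> bool:
        r, c = self.row_range, self.col_range
        return r[0] >= 0 and c[0] >= 0 and r[1] <= n_bins and c[1] <= n_bins


class WindowList(list):
    """A list of WindowSpec with per-reason drop counts attached."""

    def __init__(self, specs: Iterable = (), drops: dict | None = None):
        super().__init__(specs)
        self.drops: dict = dict(drops or {})


def flank_bins(flank_bp: int, resolution: int) -> int:
    """Convert a base-pair flank to whole bins, rounding up (logged)."""
    f = -(-flank_bp // resolution)
    if f * resolution != flank_bp:
        logger.info(
            "flank %d bp rounded up to %d bins (%d bp) at %d bp resolution",
            flank_bp,
            f,
            f * resolution,
            resolution,
        )
    return f


def _raise_if_empty(specs: WindowList, context: str) -> WindowList:
    if not specs:
        raise NoUsableWindowsError(
            f"no usable windows for {context}; drops per reason: {specs.drops or '{}'}"
        )
    return specs


def _sep_ok(sep_bp: float, min_sep: float, max_sep: float) -> bool:
    return min_sep <= sep_bp <= max_sep


def pairs_from_bedpe(
    pairs: PairSet,
    flank_bp: int,
    genome: BinnedGenome,
    min_sep: float = 0,
    max_sep: float = math.inf,
) -> WindowList:
    """One off-diagonal window per retained anchor pair (aggregate loops)."""
    f = flank_bins(flank_bp, genome.resolution)
    res = genome.resolution
    out = WindowList(drops={"separation": 0, "edge": 0})
    for idx, rec in enumerate(pairs.table.itertuples()):
        b1, b2 = rec.center_bin1, rec.center_bin2
        if not _sep_ok((b2 - b1) * res, min_sep, max_sep):
            out.drops["separation"] += 1
            continue
        spec = WindowSpec(rec.chrom, b1, b2, flank=f, kind="pair", source_ids=(idx,))
        if not spec.in_range(genome.n_bins(rec.chrom)):
            out.drops["edge"] += 1
            continue
        out.append(spec)
    return _raise_if_empty(out, "bedpe pairs")


def _pairwise(
    centers_a: Sequence,
    ids_a: Sequence,
    centers_b: Sequence,
    ids_b: Sequence,
    chrom: str,
    f: int,
    n_bins: int,
    res: int,
    min_sep: float,
    max_sep: float,
    out: WindowList,
    same_set: bool,
) -> None:
    for x, (ca, ia) in enumerate(zip(centers_a, ids_a)):
        start = x + 1 if same_set else 0
        for cb, ib in zip(centers_b[start:], ids_b[start:]):
            if same_set and ca == cb:
                continue  # self-pair at identical center
            b1, b2 = (ca, cb) if ca <= cb else (cb, ca)
            if b1 == b2 and not same_set:
                continue  # identical coordinates across sets: self-pair
            if not _sep_ok((b2 - b1) * res, min_sep, max_sep):
                out.drops["separation"] += 1
                continue
            spec = WindowSpec(
                chrom, b1, b2, flank=f, kind="pair", source_ids=(ia, ib)
            )
            if not spec.in_range(n_bins):
                out.drops["edge"] += 1
                continue
            out.append(spec)


def combinations_from_regions(
    regions: RegionSet,
    flank_bp: int,
    min_sep: float = 0,
    max_sep: float = math.inf,
) -> WindowList:
    """All unordered intra-chromosomal pairs of one region set, in band.

    Self-pairs (a region against itself) are excluded: they sit on the
    diagonal and would contaminate the off-diagonal average.
    """
    genome = regions.genome
    f = flank_bins(flank_bp, genome.resolution)
    out = WindowList(drops={"separation": 0, "edge": 0})
    for chrom in genome.chrom_names:
        sub = regions.by_chrom(chrom)
        centers = sub["center_bin"].to_list()
        ids = sub.index.to_list()
        _pairwise(
            centers,
            ids,
            centers,
            ids,
            chrom,
            f,
            genome.n_bins(chrom),
            genome.resolution,
            min_sep,
            max_sep,
            out,
            same_set=True,
        )
    return _raise_if_empty(out, "region combinations")


def cross_pairs(
    set_a: RegionSet,
    set_b: RegionSet,
    flank_bp: int,
    min_sep: float = 0,
    max_sep: float = math.inf,
) -> WindowList:
    """Every intra-chromosomal (a, b) pair between two region sets, in band."""
    genome = set_a.genome
    f = flank_bins(flank_bp, genome.resolution)
    out = WindowList(drops={"separation": 0, "edge": 0})
    seen = set()
    for chrom in genome.chrom_names:
        sub_a = set_a.by_chrom(chrom)
        sub_b = set_b.by_chrom(chrom)
        for ia, ca in zip(sub_a.index, sub_a["center_bin"]):
            for ib, cb in zip(sub_b.index, sub_b["center_bin"]):
                if ca == cb:
                    continue  # identical-coordinate self-pair
                b1, b2 = (ca, cb) if ca <= cb else (cb, ca)
                key = (chrom, b1, b2)
                if key in seen:
                    continue  # duplicate (a,b)/(b,a) orientation
                if not _sep_ok((b2 - b1) * genome.resolution, min_sep, max_sep):
                    out.drops["separation"] += 1
                    continue
                spec = WindowSpec(
                    chrom, b1, b2, flank=f, kind="pair", source_ids=(ia, ib)
                )
                if not spec.in_range(genome.n_bins(chrom)):
                    out.drops["edge"] += 1
                    continue
                seen.add(key)
                out.append(spec)
    return _raise_if_empty(out, "cross pairs")


def local_windows(regions: RegionSet, flank_bp: int) -> WindowList:
    """On-diagonal windows centered on each region (local pile-ups)."""
    genome = regions.genome
    f = flank_bins(flank_bp, genome.resolution)
    out = WindowList(drops={"edge": 0})
    for idx, rec in enumerate(regions.table.itertuples()):
        b = rec.center_bin
        spec = WindowSpec(rec.chrom, b, b, flank=f, kind="local", source_ids=(idx,))
        if not spec.in_range(genome.n_bins(rec.chrom)):
            out.drops["edge"] += 1
            continue
        out.append(spec)
    return _raise_if_empty(out, "local windows")


def rescaled_windows(
    regions: RegionSet,
    pad_fraction: float = 1.0,
    target_size_bins: int = 99,
) -> WindowList:
    """Variable-span on-diagonal windows for rescaled (e.g. TAD) pile-ups.

    Each region's extent is expanded by ``pad_fraction`` of its own length on
    each side; the resulting span is extracted at native size and later
    rescaled to ``target_size_bins`` so domains of different sizes average
    into one matrix.
    """
    if target_size_bins % 2 == 0:
        raise ValueError("target_size_bins must be odd")
    genome = regions.genome
    res = genome.resolution
    out = WindowList(drops={"edge": 0, "too_short": 0})
    for idx, rec in enumerate(regions.table.itertuples()):
        start_b = rec.start // res
        end_b = -(-rec.end // res)  # ceil: cover the full extent
        length = end_b - start_b
        if length < 1:
            out.drops["too_short"] += 1
            continue
        pad = int(round(pad_fraction * length))
        lo, hi = start_b - pad, end_b + pad
        if lo < 0 or hi > genome.n_bins(rec.chrom):
            out.drops["edge"] += 1
            continue
        center = (lo + hi) // 2
        out.append(
            WindowSpec(
                rec.chrom,
                center,
                center,
                span_i=(lo, hi),
                span_j=(lo, hi),
                kind="rescaled",
                source_ids=(idx,),
            )
        )
    return _raise_if_empty(out, "rescaled windows")


def anchored_pairs(
    anchor_index: int,
    regions: RegionSet,
    flank_bp: int,
    min_sep: float = 0,
    max_sep: float = math.inf,
) -> WindowList:
    """Windows of one anchor region against all partners in band.

    The anchor is excluded from its own partner list. Windows whose anchor is
    the downstream member are flagged for transposition so the anchor always
    occupies the row axis of the pile-up (one fixed side of the plot). An
    anchor with no in-band partners returns an empty list (the caller records
    a missing score) rather than raising.
    """
    genome = regions.genome
    f = flank_bins(flank_bp, genome.resolution)
    res = genome.resolution
    anchor = regions.table.loc[anchor_index]
    chrom = anchor["chrom"]
    ca = int(anchor["center_bin"])
    n_bins = genome.n_bins(chrom)
    out = WindowList(drops={"separation": 0, "edge": 0, "self": 0})
    sub = regions.by_chrom(chrom)
    for idx, cb in zip(sub.index, sub["center_bin"]):
        if idx == anchor_index or cb == ca:
            out.drops["self"] += idx != anchor_index
            continue
        b1, b2 = (ca, cb) if ca <= cb else (cb, ca)
        if not _sep_ok((b2 - b1) * res, min_sep, max_sep):
            out.drops["separation"] += 1
            continue
        spec = WindowSpec(
            chrom,
            b1,
            b2,
            flank=f,
            kind="pair",
            source_ids=(anchor_index, idx),
            transpose=ca > cb,  # anchor downstream: flip onto the row axis
        )
        if not spec.in_range(n_bins):
            out.drops["edge"] += 1
            continue
        out.append(spec)
    return out


def subset_sample(stream: Sequence, n: int, seed: int) -> WindowList:
    """Uniform random subset of exactly ``min(n, total)`` windows.

    Deterministic for a given seed; original stream order is preserved. With
    ``n >= total`` the stream is returned unchanged.
    """
    specs = list(stream)
    drops = getattr(stream, "drops", {})
    if n >= len(specs):
        return WindowList(specs, drops)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(specs), size=n, replace=False))
    return WindowList([specs[i] for i in idx], drops)
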