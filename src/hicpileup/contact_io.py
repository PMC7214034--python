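"""Input/output layer: binned-genome data model and every external format.

The central container is :class:`ContactMatrix`, a per-chromosome sparse
upper-triangular store of raw Hi-C counts with optional balancing weights.
Matrices are loaded lazily, one bulk fetch per chromosome, so a whole-genome
file is never materialized.

Supported formats:

* single-resolution cooler-schema HDF5 (``.cool``) — read here, written by
  :mod:`hicpileup.synthetic`;
* BED (>= 3 columns) region files and BEDPE (>= 6 columns) pair files;
* long-format expected TSV (chrom, diagonal, value), the layout produced by
  ``cooltools compute-expected``;
* plain-text pile-up matrices with ``#``-prefixed metadata lines.

Coordinates are 0-based half-open throughout; a region's representative bin
is ``floor(midpoint / resolution)``.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedGenome",
    "ContactMatrix",
    "RegionSet",
    "PairSet",
    "ExpectedProfile",
    "FormatError",
    "NoRegionsError",
    "read_cool",
    "read_regions",
    "read_pairs",
    "read_expected",
    "write_pileup_text",
    "read_pileup_text",
]


class FormatError(ValueError):
    """An input file does not follow the expected layout."""


class NoRegionsError(ValueError):
    """A region/pair file yielded no usable records."""


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinnedGenome:
    """A genome divided into fixed-size bins at a single resolution.

    Bin ``k`` of a chromosome covers ``[k*resolution, min((k+1)*resolution,
    length))`` in 0-based half-open base-pair coordinates.
    """

    chrom_names: tuple
    chrom_lengths: tuple
    resolution: int

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(
            self, "_lengths", dict(zip(self.chrom_names, self.chrom_lengths))
        )

    @classmethod
    def from_dict(cls, lengths: dict, resolution: int) -> "BinnedGenome":
        return cls(tuple(lengths), tuple(lengths.values()), resolution)

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def n_bins(self, chrom: str) -> int:
        return -(-self._lengths[chrom] // self.resolution)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_names)

    def bin_offsets(self) -> dict:
        """Global bin-id offset of each chromosome (cooler bin table order)."""
        out, off = {}, 0
        for c in self.chrom_names:
            out[c] = off
            off += self.n_bins(c)
        return out

    def bin_of(self, chrom: str, pos: int) -> int:
        return pos // self.resolution


# ---------------------------------------------------------------------------
# contact matrix
# ---------------------------------------------------------------------------


class ContactMatrix:
    """Per-chromosome sparse upper-triangular raw counts plus weights.

    Only pixels with ``bin_i <= bin_j`` are stored; queries reflect across the
    diagonal. ``balanced_value(i, j) = count * w_i * w_j``; a bin with a
    non-finite weight renders its entire row and column missing (NaN), which
    distinguishes unmappable bins from genuinely zero contact.

    ``loader(chrom)`` must return ``(row, col, count)`` triplet arrays in
    local bin coordinates; it is called at most once per chromosome and the
    number of calls is recorded in :attr:`fetch_counts`.
    """

    def __init__(
        self,
        genome: BinnedGenome,
        loader: Callable[[str], tuple],
        weights: dict | None = None,
    ):
        self.genome = genome
        self._loader = loader
        self.weights = weights  # chrom -> float array (NaN = invalid) or None
        self._sym: dict = {}
        self._upper: dict = {}
        self.fetch_counts: dict = {c: 0 for c in genome.chrom_names}

    @classmethod
    def from_triplets(
        cls,
        genome: BinnedGenome,
        triplets: dict,
        weights: dict | None = None,
    ) -> "ContactMatrix":
        """Build from in-memory ``{chrom: (row, col, count)}`` triplets."""
        return cls(genome, lambda chrom: triplets[chrom], weights)

    @property
    def has_weights(self) -> bool:
        return self.weights is not None

    def chrom_weights(self, chrom: str) -> np.ndarray:
        if self.weights is None:
            raise ValueError("contact matrix carries no balancing weights")
        return self.weights[chrom]

    def upper(self, chrom: str) -> sp.csr_matrix:
        """Upper-triangular CSR of raw counts (one fetch per chromosome)."""
        if chrom not in self._upper:
            row, col, cnt = self._loader(chrom)
            self.fetch_counts[chrom] += 1
            n = self.genome.n_bins(chrom)
            m = sp.coo_matrix(
                (np.asarray(cnt, dtype=float), (row, col)), shape=(n, n)
            ).tocsr()
            self._upper[chrom] = m
        return self._upper[chrom]

    def symmetric(self, chrom: str) -> sp.csr_matrix:
        """Full symmetric CSR of raw counts (diagonal counted once)."""
        if chrom not in self._sym:
            u = self.upper(chrom)
            d = sp.diags(u.diagonal())
            self._sym[chrom] = (u + u.T - d).tocsr()
        return self._sym[chrom]

    def coverage(self, chrom: str) -> np.ndarray:
        """Total raw contacts of each bin in the chromosome (marginal sum)."""
        return np.asarray(self.symmetric(chrom).sum(axis=1)).ravel()

    def dense(self, chrom: str, balanced: bool = False) -> np.ndarray:
        """Full dense matrix; oracle/debugging aid, not used in the pipeline."""
        m = self.symmetric(chrom).toarray()
        if balanced:
            w = self.chrom_weights(chrom)
            m = m * np.outer(w, w)
        return m

    def value(self, chrom: str, i: int, j: int, balanced: bool = False) -> float:
        v = self.symmetric(chrom)[i, j]
        if balanced:
            w = self.chrom_weights(chrom)
            v = v * w[i] * w[j]
        return float(v)


# ---------------------------------------------------------------------------
# regions and pairs
# ---------------------------------------------------------------------------


@dataclass
class RegionSet:
    """Genomic intervals with a deterministic representative (center) bin."""

    table: pd.DataFrame  # chrom, start, end, name, center_bin
    genome: BinnedGenome

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self):
        return self.table.itertuples()

    def by_chrom(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, genome: BinnedGenome) -> "RegionSet":
        df = df.copy().reset_index(drop=True)
        if "name" not in df:
            df["name"] = [f"region_{i}" for i in range(len(df))]
        mid = (df["start"] + df["end"]) // 2
        df["center_bin"] = (mid // genome.resolution).astype(int)
        return cls(df, genome)


@dataclass
class PairSet:
    """Intra-chromosomal anchor pairs, canonicalized so center1 <= center2."""

    table: pd.DataFrame  # chrom, start1, end1, start2, end2, center_bin1/2
    genome: BinnedGenome

    def __len__(self) -> int:
        return len(self.table)

    def by_chrom(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]


def _read_table(path, min_cols: int, what: str) -> pd.DataFrame:
    rows = []
    source = path
    close = False
    if path == "-":
        import sys

        handle = sys.stdin
    else:
        handle = open(path)
        close = True
    try:
        for ln, line in enumerate(handle, 1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            parts = s.split()
            if len(parts) < min_cols or not _is_int(parts[1]):
                if ln == 1:
                    continue  # tolerate a single header line of column names
                raise FormatError(
                    f"{source} line {ln}: expected >= {min_cols} whitespace-"
                    f"delimited columns with integer coordinates ({what})"
                )
            rows.append((ln, parts))
    finally:
        if close:
            handle.close()
    return rows


def _is_int(tok) -> bool:
    try:
        int(tok)
        return True
    except (TypeError, ValueError):
        return False


def read_regions(path, genome: BinnedGenome) -> RegionSet:
    """Read a BED-like file (chrom, start, end[, name]) into a RegionSet.

    Records on chromosomes absent from the genome are dropped with a logged
    count; records with start >= end are rejected with a warning.
    """
    rows = _read_table(path, 3, "BED")
    recs, dropped_chrom, dropped_coord = [], 0, 0
    for ln, p in rows:
        chrom, start, end = p[0], int(p[1]), int(p[2])
        if start >= end:
            logger.warning("%s line %d: start >= end, record rejected", path, ln)
            dropped_coord += 1
            continue
        if chrom not in genome.chrom_names:
            dropped_chrom += 1
            continue
        name = p[3] if len(p) > 3 else f"{chrom}:{start}-{end}"
        recs.append((chrom, start, end, name))
    if dropped_chrom:
        logger.info(
            "%s: dropped %d records on chromosomes absent from the genome",
            path,
            dropped_chrom,
        )
    df = pd.DataFrame(recs, columns=["chrom", "start", "end", "name"])
    return RegionSet.from_frame(df, genome)


def read_pairs(path, genome: BinnedGenome) -> PairSet:
    """Read a BEDPE file into a PairSet.

    Inter-chromosomal rows and rows on unknown chromosomes are dropped with a
    logged count; anchors are swapped where needed so center1 <= center2.
    """
    rows = _read_table(path, 6, "BEDPE")
    recs, dropped_trans, dropped_chrom, dropped_coord = [], 0, 0, 0
    res = genome.resolution
    for ln, p in rows:
        c1, s1, e1, c2, s2, e2 = p[0], int(p[1]), int(p[2]), p[3], int(p[4]), int(p[5])
        if s1 >= e1 or s2 >= e2:
            logger.warning("%s line %d: start >= end, record rejected", path, ln)
            dropped_coord += 1
            continue
        if c1 != c2:
            dropped_trans += 1
            continue
        if c1 not in genome.chrom_names:
            dropped_chrom += 1
            continue
        b1, b2 = ((s1 + e1) // 2) // res, ((s2 + e2) // 2) // res
        if b2 < b1:
            s1, e1, s2, e2 = s2, e2, s1, e1
            b1, b2 = b2, b1
        recs.append((c1, s1, e1, s2, e2, b1, b2))
    if dropped_trans:
        logger.info("%s: dropped %d inter-chromosomal pairs", path, dropped_trans)
    if dropped_chrom:
        logger.info("%s: dropped %d pairs on unknown chromosomes", path, dropped_chrom)
    df = pd.DataFrame(
        recs,
        columns=["chrom", "start1", "end1", "start2", "end2", "center_bin1", "center_bin2"],
    )
    return PairSet(df, genome)


# ---------------------------------------------------------------------------
# expected profiles
# ---------------------------------------------------------------------------


@dataclass
class ExpectedProfile:
    """Per-chromosome mean contact value at each diagonal offset.

    ``profiles[chrom][k]`` is the average (balanced, unless computed on raw
    counts) contact at separation ``k`` bins; NaN marks missing diagonals.
    """

    profiles: dict  # chrom -> float array of length n_bins(chrom)
    value_column: str = "balanced.avg"

    def d(self, chrom: str) -> np.ndarray:
        return self.profiles[chrom]


def read_expected(
    path,
    genome: BinnedGenome,
    value_column: str = "balanced.avg",
) -> ExpectedProfile:
    """Read a long-format expected TSV (cooltools compute-expected layout).

    The chromosome column may be named ``chrom`` or ``region``; the diagonal
    column ``diag`` or ``dist``. Missing diagonals become NaN. A chromosome
    name present in the table but not in the genome raises an error naming
    both spellings.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    chrom_col = next((c for c in ("chrom", "region", "region1") if c in df), None)
    diag_col = next((c for c in ("diag", "dist") if c in df), None)
    if chrom_col is None or diag_col is None:
        raise FormatError(
            f"{path}: need a chromosome column (chrom/region) and a diagonal "
            f"column (diag/dist); found {list(df.columns)}"
        )
    if value_column not in df:
        raise FormatError(
            f"{path}: value column {value_column!r} not found; columns are "
            f"{list(df.columns)}"
        )
    unknown = sorted(set(df[chrom_col].astype(str)) - set(genome.chrom_names))
    if unknown:
        raise FormatError(
            f"{path}: chromosome name(s) {unknown} not in genome "
            f"{list(genome.chrom_names)}; names must match exactly "
            "(no automatic 'chr' prefix reconciliation)"
        )
    profiles = {}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        d = np.full(n, np.nan)
        sub = df[df[chrom_col].astype(str) == chrom]
        diag = sub[diag_col].to_numpy(dtype=int)
        ok = (diag >= 0) & (diag < n)
        d[diag[ok]] = sub[value_column].to_numpy(dtype=float)[ok]
        profiles[chrom] = d
    return ExpectedProfile(profiles, value_column)


# ---------------------------------------------------------------------------
# cooler-schema reader
# ---------------------------------------------------------------------------


def _open_cool_group(f: h5py.File, path, resolution):
    if "pixels" in f:
        return f
    if "resolutions" in f:
        if resolution is None:
            avail = sorted(f["resolutions"], key=int)
            raise FormatError(
                f"{path} is a multi-resolution container; pass resolution= "
                f"(available: {avail})"
            )
        key = f"resolutions/{int(resolution)}"
        if key not in f:
            raise FormatError(f"{path}: resolution {resolution} not present")
        return f[key]
    raise FormatError(f"{path}: not a cooler-schema file (no pixels table)")


def read_cool(
    path,
    use_weights: bool = True,
    weight_column: str = "weight",
    resolution: int | None = None,
) -> ContactMatrix:
    """Open a single-resolution cooler-schema HDF5 file lazily.

    Per-chromosome sparse matrices are fetched on first access, in one bulk
    read per chromosome (via the ``indexes/bin1_offset`` index). With
    ``use_weights`` the balancing weight column (default ``weight``) is
    loaded; its absence is a configuration error naming the column.
    """
    if not os.path.exists(path):
        raise OSError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        grp = _open_cool_group(f, path, resolution)
        names = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in grp["chroms/name"][:]
        ]
        lengths = [int(x) for x in grp["chroms/length"][:]]
        binsize = int(grp.attrs.get("bin-size", 0)) or None
        if binsize is None:
            starts = grp["bins/start"][:2]
            binsize = int(starts[1] - starts[0]) if len(starts) > 1 else int(
                grp["bins/end"][0]
            )
        genome = BinnedGenome(tuple(names), tuple(lengths), binsize)
        offsets = genome.bin_offsets()
        weights = None
        if use_weights:
            if f"bins/{weight_column}" not in grp:
                raise FormatError(
                    f"{path}: balancing requested but bins table has no "
                    f"{weight_column!r} column; pass use_weights=False or the "
                    "correct weight column name"
                )
            wall = grp[f"bins/{weight_column}"][:].astype(float)
            weights = {
                c: wall[offsets[c] : offsets[c] + genome.n_bins(c)] for c in names
            }
        grp_path = grp.name

    def loader(chrom: str):
        with h5py.File(path, "r") as fh:
            g = fh[grp_path]
            lo = offsets[chrom]
            hi = lo + genome.n_bins(chrom)
            b1o = g["indexes/bin1_offset"][:]
            p0, p1 = int(b1o[lo]), int(b1o[hi])
            bin1 = g["pixels/bin1_id"][p0:p1]
            bin2 = g["pixels/bin2_id"][p0:p1]
            count = g["pixels/count"][p0:p1]
        cis = bin2 < hi  # drop trans pixels
        return bin1[cis] - lo, bin2[cis] - lo, count[cis]

    return ContactMatrix(genome, loader, weights)


# ---------------------------------------------------------------------------
# pile-up text output
# ---------------------------------------------------------------------------


def write_pileup_text(pileup, path) -> None:
    """Write a finalized pile-up as a plain-text matrix.

    ``#``-prefixed metadata lines record the window count, resolution, flank
    or target size, normalization mode and seed; missing pixels are written
    as ``nan``. The file round-trips through :func:`read_pileup_text`.
    """
    meta = dict(pileup.metadata)
    meta["n_windows"] = pileup.n_windows
    with open(path, "w") as fh:
        for k in sorted(meta):
            fh.write(f"# {k}: {meta[k]}\n")
        np.savetxt(fh, pileup.matrix, fmt="%.10g")


def read_pileup_text(path):
    """Read a matrix written by :func:`write_pileup_text`; returns (matrix, meta)."""
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
        elif line.strip():
            body.append(line)
    mat = np.loadtxt(body) if body else np.empty((0, 0))
    if mat.ndim == 1:
        mat = mat[None, :]
    return mat, meta
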