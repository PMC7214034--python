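"""Synthetic Hi-C contact maps with known ground truth.

The generator emulates the structure pile-up analysis assumes: a power-law
decay of contact probability with genomic distance, focal loop enrichments
(dots), block-like enriched domains, multiplicative per-bin visibility
biases, Poisson-sampled counts and cooler-style balancing weights. The
intensity surface is

    lambda(i, j) = depth_scale * b_i * b_j * decay(|i - j|)
                   * loop_factor(i, j) * domain_factor(i, j)

with ``decay(k) = diagonal_value * k**(-alpha)`` for ``k >= 1`` and
``decay(0) = 2 * decay(1)`` (the self-interaction diagonal is excluded from
all off-diagonal analyses anyway). Counts are drawn once per upper-triangle
pixel; the same seed always yields a byte-identical pixel table.

What it does not emulate: compartment checkerboards, trans contacts,
overdispersion beyond Poisson, fragment-level artefacts. Sparse single-cell
depth is approximated by a small ``depth_scale``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .contact_io import BinnedGenome, ContactMatrix

__all__ = [
    "PlantedLoop",
    "PlantedDomain",
    "SyntheticSpec",
    "GroundTruth",
    "simulate_contacts",
    "plant_loops",
    "plant_tads",
    "random_loop_sites",
    "write_cool_fixture",
]


@dataclass(frozen=True)
class PlantedLoop:
    chrom: str
    bin_i: int
    bin_j: int
    fold: float
    footprint: int = 1
    blur_sigma: float = 0.0  # bins; 0 = hard square footprint


@dataclass(frozen=True)
class PlantedDomain:
    chrom: str
    bin_start: int
    bin_end: int  # half-open
    fold: float


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one simulated multi-chromosome contact map."""

    chrom_lengths: tuple  # ((name, bp), ...)
    resolution: int
    decay_exponent: float = 1.0
    diagonal_value: float = 100.0
    depth_scale: float = 1.0
    loops: tuple = ()
    domains: tuple = ()
    bias_sd: float = 0.0  # lognormal sigma of per-bin bias; 0 = unbiased
    invalid_bins: tuple = ()  # ((chrom, bin), ...) -> NaN weight
    weight_mode: str = "exact"  # exact | iterative | none
    seed: int = 0

    def genome(self) -> BinnedGenome:
        names = tuple(n for n, _ in self.chrom_lengths)
        lengths = tuple(l for _, l in self.chrom_lengths)
        return BinnedGenome(names, lengths, self.resolution)

    def validate(self) -> None:
        g = self.genome()
        for lp in self.loops:
            if lp.fold <= 0 or lp.footprint < 1:
                raise ValueError(f"invalid loop {lp}")
            n = g.n_bins(lp.chrom)
            if not (0 <= lp.bin_i < n and 0 <= lp.bin_j < n):
                raise ValueError(f"loop {lp} out of range")
        for dm in self.domains:
            if dm.fold <= 0:
                raise ValueError(f"invalid domain {dm}")
            n = g.n_bins(dm.chrom)
            if not (0 <= dm.bin_start < dm.bin_end <= n):
                raise ValueError(f"domain {dm} out of range")


def plant_loops(spec: SyntheticSpec, loops) -> SyntheticSpec:
    """Return a spec with extra focal enrichments (multiplicative stacking)."""
    return replace(spec, loops=spec.loops + tuple(loops))


def plant_tads(spec: SyntheticSpec, domains) -> SyntheticSpec:
    """Return a spec with extra enriched square domains."""
    return replace(spec, domains=spec.domains + tuple(domains))


@dataclass
class GroundTruth:
    """Everything needed to check recovery without re-deriving the recipe."""

    spec: SyntheticSpec
    genome: BinnedGenome
    decay: dict  # chrom -> per-diagonal expected (unbiased, depth-scaled)
    lam: dict  # chrom -> dense intensity surface (with bias)
    bias: dict  # chrom -> per-bin multiplicative bias
    factor: dict  # chrom -> combined loop*domain fold surface

    def expected_balanced(self, chrom: str) -> np.ndarray:
        """Intensity surface after perfect bias removal."""
        b = self.bias[chrom]
        return self.lam[chrom] / np.outer(b, b)


def _decay_vector(n: int, alpha: float, diagonal_value: float) -> np.ndarray:
    d = np.empty(n)
    k = np.arange(1, n)
    d[1:] = diagonal_value * k.astype(float) ** (-alpha)
    d[0] = 2.0 * diagonal_value
    return d


def _fold_surface(spec: SyntheticSpec, chrom: str, n: int) -> np.ndarray:
    f = np.ones((n, n))
    for dm in spec.domains:
        if dm.chrom != chrom:
            continue
        f[dm.bin_start : dm.bin_end, dm.bin_start : dm.bin_end] *= dm.fold
    for lp in spec.loops:
        if lp.chrom != chrom:
            continue
        if lp.blur_sigma > 0:
            # Gaussian dot, fold preserved at the center
            r = int(np.ceil(3 * lp.blur_sigma))
            ii = np.arange(max(lp.bin_i - r, 0), min(lp.bin_i + r + 1, n))
            jj = np.arange(max(lp.bin_j - r, 0), min(lp.bin_j + r + 1, n))
            gi = np.exp(-0.5 * ((ii - lp.bin_i) / lp.blur_sigma) ** 2)
            gj = np.exp(-0.5 * ((jj - lp.bin_j) / lp.blur_sigma) ** 2)
            patch = 1.0 + (lp.fold - 1.0) * np.outer(gi, gj)
            f[np.ix_(ii, jj)] *= patch
            f[np.ix_(jj, ii)] *= patch.T
        else:
            h = lp.footprint // 2
            i0, i1 = max(lp.bin_i - h, 0), min(lp.bin_i + h + 1, n)
            j0, j1 = max(lp.bin_j - h, 0), min(lp.bin_j + h + 1, n)
            f[i0:i1, j0:j1] *= lp.fold
            f[j0:j1, i0:i1] *= lp.fold
    return f


def _iterative_weights(counts_sym: np.ndarray, tol: float = 1e-6, max_iter: int = 2000):
    """Matrix-balancing weights: iterate w_i <- w_i / sqrt(rel. marginal)."""
    n = counts_sym.shape[0]
    w = np.ones(n)
    valid = counts_sym.sum(axis=1) > 0
    w[~valid] = np.nan
    for _ in range(max_iter):
        bal = counts_sym * np.outer(np.where(valid, w, 0), np.where(valid, w, 0))
        m = bal.sum(axis=1)
        mv = m[valid]
        rel = mv / mv.mean()
        if np.abs(rel - 1).max() < tol:
            break
        w[valid] /= np.sqrt(rel)
    return w


def simulate_contacts(spec: SyntheticSpec):
    """Sample a contact map from the recipe; returns (matrix, ground_truth)."""
    spec.validate()
    genome = spec.genome()
    rng = np.random.default_rng(spec.seed)
    triplets, weights = {}, {}
    decay_d, lam_d, bias_d, factor_d = {}, {}, {}, {}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        d = _decay_vector(n, spec.decay_exponent, spec.diagonal_value)
        if spec.bias_sd > 0:
            b = np.exp(rng.normal(0.0, spec.bias_sd, size=n))
        else:
            b = np.ones(n)
        offs = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        factor = _fold_surface(spec, chrom, n)
        lam = spec.depth_scale * np.outer(b, b) * d[offs] * factor
        iu, ju = np.triu_indices(n)
        counts = rng.poisson(lam[iu, ju])
        nz = counts > 0
        triplets[chrom] = (iu[nz], ju[nz], counts[nz])
        if spec.weight_mode == "exact":
            w = 1.0 / b
        elif spec.weight_mode == "iterative":
            c = np.zeros((n, n))
            c[iu, ju] = counts
            c = c + c.T - np.diag(np.diag(c))
            w = _iterative_weights(c)
        elif spec.weight_mode == "none":
            w = None
        else:
            raise ValueError(f"unknown weight_mode {spec.weight_mode!r}")
        if w is not None:
            for ch, bad in spec.invalid_bins:
                if ch == chrom:
                    w[bad] = np.nan
            weights[chrom] = w
        decay_d[chrom] = spec.depth_scale * d
        lam_d[chrom] = lam
        bias_d[chrom] = b
        factor_d[chrom] = factor
    matrix = ContactMatrix.from_triplets(
        genome, triplets, weights if spec.weight_mode != "none" else None
    )
    truth = GroundTruth(spec, genome, decay_d, lam_d, bias_d, factor_d)
    return matrix, truth


def random_loop_sites(
    genome: BinnedGenome,
    n: int,
    rng: np.random.Generator,
    min_sep_bins: int,
    max_sep_bins: int,
    margin_bins: int,
    min_dist_bins: int = 4,
):
    """Uniformly placed intra-chromosomal bin pairs, clear of the edges.

    Convenience for building planted-loop specs and their BEDPE files; pairs
    are spread across chromosomes proportionally to their usable size. Sites
    on the same chromosome keep a Chebyshev distance of at least
    ``min_dist_bins`` in the (bin_i, bin_j) plane so planted footprints
    never overlap (overlapping folds would stack multiplicatively).
    """
    chroms = list(genome.chrom_names)
    sizes = np.array([max(genome.n_bins(c) - 2 * margin_bins, 0) for c in chroms], float)
    if sizes.sum() <= 0:
        raise ValueError("no chromosome has room for the requested margin")
    probs = sizes / sizes.sum()
    out = []
    placed: dict = {c: [] for c in chroms}
    for _ in range(n):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        nb = genome.n_bins(chrom)
        for _attempt in range(2000):
            sep = int(rng.integers(min_sep_bins, max_sep_bins + 1))
            lo, hi = margin_bins, nb - margin_bins - sep
            if hi <= lo:
                continue
            bi = int(rng.integers(lo, hi))
            bj = bi + sep
            if any(
                max(abs(bi - pi), abs(bj - pj)) < min_dist_bins
                for pi, pj in placed[chrom]
            ):
                continue
            placed[chrom].append((bi, bj))
            out.append((chrom, bi, bj))
            break
        else:
            raise ValueError("could not place a loop within the margins")
    return out


# ---------------------------------------------------------------------------
# cooler-schema writer
# ---------------------------------------------------------------------------


def write_cool_fixture(
    matrix: ContactMatrix,
    path,
    include_weights: bool = True,
    ground_truth: GroundTruth | None = None,
) -> None:
    """Write a ContactMatrix as a single-resolution cooler-schema HDF5 file.

    Produces the standard table layout (chroms, bins, pixels, indexes) with
    ``symmetric-upper`` storage so the file round-trips through
    :func:`hicpileup.contact_io.read_cool`. Optionally writes a ground-truth
    JSON sidecar (``<path>.truth.json``) for a simulated matrix.
    """
    genome = matrix.genome
    offsets = genome.bin_offsets()
    names = list(genome.chrom_names)
    n_bins_total = genome.total_bins

    bin_chrom = np.concatenate(
        [np.full(genome.n_bins(c), k, dtype=np.int32) for k, c in enumerate(names)]
    )
    starts, ends = [], []
    for c in names:
        nb = genome.n_bins(c)
        s = np.arange(nb, dtype=np.int64) * genome.resolution
        e = np.minimum(s + genome.resolution, genome.length(c))
        starts.append(s)
        ends.append(e)
    bin_start = np.concatenate(starts)
    bin_end = np.concatenate(ends)

    b1_parts, b2_parts, cnt_parts = [], [], []
    for c in names:
        row, col, cnt = matrix._loader(c)
        order = np.lexsort((col, row))
        b1_parts.append(np.asarray(row)[order] + offsets[c])
        b2_parts.append(np.asarray(col)[order] + offsets[c])
        cnt_parts.append(np.asarray(cnt)[order])
    bin1 = np.concatenate(b1_parts).astype(np.int64)
    bin2 = np.concatenate(b2_parts).astype(np.int64)
    count = np.concatenate(cnt_parts).astype(np.int32)

    chrom_enum = h5py.enum_dtype({n: k for k, n in enumerate(names)}, basetype="i4")
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["format-version"] = 3
        f.attrs["bin-type"] = "fixed"
        f.attrs["bin-size"] = genome.resolution
        f.attrs["storage-mode"] = "symmetric-upper"
        f.attrs["nchroms"] = len(names)
        f.attrs["nbins"] = n_bins_total
        f.attrs["nnz"] = len(count)
        g = f.create_group("chroms")
        g.create_dataset("name", data=np.array(names, dtype="S32"))
        g.create_dataset(
            "length", data=np.array([genome.length(c) for c in names], dtype=np.int64)
        )
        g = f.create_group("bins")
        g.create_dataset("chrom", data=bin_chrom, dtype=chrom_enum)
        g.create_dataset("start", data=bin_start)
        g.create_dataset("end", data=bin_end)
        if include_weights and matrix.has_weights:
            w = np.concatenate([matrix.chrom_weights(c) for c in names])
            g.create_dataset("weight", data=w.astype(np.float64))
        g = f.create_group("pixels")
        g.create_dataset("bin1_id", data=bin1)
        g.create_dataset("bin2_id", data=bin2)
        g.create_dataset("count", data=count)
        g = f.create_group("indexes")
        chrom_offset = np.zeros(len(names) + 1, dtype=np.int64)
        for k, c in enumerate(names):
            chrom_offset[k + 1] = chrom_offset[k] + genome.n_bins(c)
        g.create_dataset("chrom_offset", data=chrom_offset)
        bin1_offset = np.searchsorted(bin1, np.arange(n_bins_total + 1))
        g.create_dataset("bin1_offset", data=bin1_offset.astype(np.int64))

    if ground_truth is not None:
        sidecar = {
            "resolution": genome.resolution,
            "chrom_lengths": {c: genome.length(c) for c in names},
            "decay_exponent": ground_truth.spec.decay_exponent,
            "diagonal_value": ground_truth.spec.diagonal_value,
            "depth_scale": ground_truth.spec.depth_scale,
            "seed": ground_truth.spec.seed,
            "bias_sd": ground_truth.spec.bias_sd,
            "loops": [
                dict(chrom=l.chrom, bin_i=l.bin_i, bin_j=l.bin_j, fold=l.fold,
                     footprint=l.footprint, blur_sigma=l.blur_sigma)
                for l in ground_truth.spec.loops
            ],
            "domains": [
                dict(chrom=d.chrom, bin_start=d.bin_start, bin_end=d.bin_end,
                     fold=d.fold)
                for d in ground_truth.spec.domains
            ],
        }
        with open(f"{path}.truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)
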