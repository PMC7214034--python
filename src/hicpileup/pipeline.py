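"""High-level orchestration: config validation, per-chromosome pipelines,
optional multiprocessing, and output writing.

Work is partitioned by chromosome: each chromosome's windows are extracted
and accumulated independently (the file is read once per chromosome), then
per-chromosome accumulators are merged and finalized. Per-chromosome random
streams are derived deterministically from the run seed and the chromosome
name, so a run with 1 process equals a run with N processes to within float
summation order (< 1e-12).
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass
from multiprocessing import get_context

import numpy as np

from . import contact_io, pairing, scoring
from .contact_io import ContactMatrix, ExpectedProfile, read_cool
from .normalization import (
    NormalizerMatrix,
    apply_normalizer,
    compute_expected,
    control_normalizer,
    control_specs_for_stream,
    coverage_normalize,
    expected_normalizer,
)
from .pairing import NoUsableWindowsError, WindowList
from .pileup_core import (
    Pileup,
    finalize_mean,
    merge_accumulators,
    pileup_windows,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pileup", "run_loopability", "chrom_rng"]

MODES = ("pairs", "combinations", "cross", "local", "rescaled")


@dataclass
class RunConfig:
    """Everything one pile-up run needs; validated before any compute."""

    cool_path: str
    mode: str
    pairs_path: str | None = None
    regions_path: str | None = None
    regions2_path: str | None = None
    flank_bp: int = 100_000
    pad_fraction: float = 1.0
    target_size: int = 99
    min_sep: float = 0.0
    max_sep: float = math.inf
    expected_path: str | None = None
    nshifts: int | None = None
    balanced: bool = True
    coverage_norm: bool = False
    subset: int | None = None
    chroms: tuple | None = None
    n_processes: int = 1
    seed: int = 0
    out_path: str | None = None
    weight_column: str = "weight"
    min_shift_bins: int | None = None
    expected_value_column: str = "balanced.avg"
    compute_expected_if_missing: bool = True

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.expected_path is not None and self.nshifts is not None:
            raise ValueError(
                "--expected and --nshifts are mutually exclusive: pick one "
                "normalization strategy"
            )
        if self.mode == "pairs" and not self.pairs_path:
            raise ValueError("mode 'pairs' requires a BEDPE path")
        if self.mode in ("combinations", "local", "rescaled") and not self.regions_path:
            raise ValueError(f"mode {self.mode!r} requires a BED path")
        if self.mode == "cross" and not (self.regions_path and self.regions2_path):
            raise ValueError("mode 'cross' requires two BED paths")
        if self.nshifts is not None and self.nshifts < 1:
            raise ValueError("nshifts must be >= 1")

    @property
    def normalization(self) -> str:
        if self.expected_path is not None or (
            self.nshifts is None and self.compute_expected_if_missing
        ):
            return "expected"
        if self.nshifts is not None:
            return "shifted_controls"
        return "none"


def chrom_rng(seed: int, chrom: str) -> np.random.Generator:
    """Deterministic per-chromosome random stream (parallel == serial)."""
    tag = zlib.crc32(chrom.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def build_windows(config: RunConfig, genome) -> WindowList:
    """Enumerate the window stream for the configured mode."""
    if config.mode == "pairs":
        pairs = contact_io.read_pairs(config.pairs_path, genome)
        specs = pairing.pairs_from_bedpe(
            pairs, config.flank_bp, genome, config.min_sep, config.max_sep
        )
    elif config.mode == "combinations":
        regions = contact_io.read_regions(config.regions_path, genome)
        specs = pairing.combinations_from_regions(
            regions, config.flank_bp, config.min_sep, config.max_sep
        )
    elif config.mode == "cross":
        a = contact_io.read_regions(config.regions_path, genome)
        b = contact_io.read_regions(config.regions2_path, genome)
        specs = pairing.cross_pairs(
            a, b, config.flank_bp, config.min_sep, config.max_sep
        )
    elif config.mode == "local":
        regions = contact_io.read_regions(config.regions_path, genome)
        specs = pairing.local_windows(regions, config.flank_bp)
    elif config.mode == "rescaled":
        regions = contact_io.read_regions(config.regions_path, genome)
        specs = pairing.rescaled_windows(
            regions, config.pad_fraction, config.target_size
        )
    else:  # pragma: no cover - guarded by validate()
        raise ValueError(config.mode)
    if config.chroms:
        kept = WindowList(
            [s for s in specs if s.chrom in config.chroms], specs.drops
        )
        kept.drops["chrom_filter"] = len(specs) - len(kept)
        if not kept:
            raise NoUsableWindowsError(
                f"no windows left after chromosome filter {config.chroms}; "
                f"drops: {kept.drops}"
            )
        specs = kept
    if config.subset is not None:
        specs = pairing.subset_sample(specs, config.subset, config.seed)
    return specs


def _chrom_task(args):
    """Per-chromosome worker: observed + normalizer accumulators."""
    (cool_path, weight_column, chrom, specs, opts, expected_d) = args
    use_weights = opts["balanced"]
    matrix = read_cool(cool_path, use_weights=use_weights, weight_column=weight_column)
    rescale_target = opts["rescale_target"]
    acc = pileup_windows(
        matrix,
        specs,
        balanced=opts["balanced"],
        coverage=opts["coverage"],
        rescale_target=rescale_target,
    )
    norm_acc = None
    ctrl_n = 0
    if opts["normalization"] == "expected":
        if expected_d is None:
            prof = compute_expected(matrix, balanced=opts["balanced"], chroms=[chrom])
            d = prof.profiles[chrom]
        else:
            d = expected_d
        prof1 = ExpectedProfile({chrom: d})
        nm = expected_normalizer(prof1, specs, rescale_target=rescale_target)
        norm_acc = nm.matrix  # mean expected window for this chromosome
        ctrl_n = len(specs)
    elif opts["normalization"] == "shifted_controls":
        rng = chrom_rng(opts["seed"], chrom)
        ctrl = control_specs_for_stream(
            specs, opts["nshifts"], matrix.genome, rng, opts["min_shift_bins"]
        )
        ctrl_acc = pileup_windows(
            matrix,
            ctrl,
            balanced=opts["balanced"],
            coverage=opts["coverage"],
            rescale_target=rescale_target,
        )
        norm_acc = ctrl_acc
        ctrl_n = len(ctrl)
    return chrom, acc, norm_acc, ctrl_n, len(specs)


def run_pileup(config: RunConfig):
    """Execute a full pile-up run; returns (Pileup, summary dict).

    Writes the finalized matrix (plain text with metadata comments) to
    ``config.out_path`` when set.
    """
    config.validate()
    matrix = read_cool(
        config.cool_path,
        use_weights=config.balanced,
        weight_column=config.weight_column,
    )
    genome = matrix.genome
    specs = build_windows(config, genome)
    rescale_target = config.target_size if config.mode == "rescaled" else None

    expected_prof = None
    if config.normalization == "expected" and config.expected_path is not None:
        expected_prof = contact_io.read_expected(
            config.expected_path, genome, config.expected_value_column
        )

    by_chrom: dict = {}
    for s in specs:
        by_chrom.setdefault(s.chrom, []).append(s)

    opts = dict(
        balanced=config.balanced,
        coverage=config.coverage_norm,
        rescale_target=rescale_target,
        normalization=config.normalization,
        nshifts=config.nshifts,
        seed=config.seed,
        min_shift_bins=config.min_shift_bins,
    )
    tasks = [
        (
            config.cool_path,
            config.weight_column,
            chrom,
            chrom_specs,
            opts,
            expected_prof.profiles[chrom] if expected_prof is not None else None,
        )
        for chrom, chrom_specs in sorted(by_chrom.items())
    ]
    if config.n_processes > 1 and len(tasks) > 1:
        with get_context("fork").Pool(min(config.n_processes, len(tasks))) as pool:
            results = pool.map(_chrom_task, tasks)
    else:
        results = [_chrom_task(t) for t in tasks]

    obs = merge_accumulators([r[1] for r in results])
    n_ctrl = sum(r[3] for r in results)

    if config.normalization == "expected":
        # weighted mean of per-chromosome mean expected windows
        total = sum(r[4] for r in results)
        mat = sum(r[2] * (r[4] / total) for r in results)
        normalizer = NormalizerMatrix(mat, "expected", 0)
    elif config.normalization == "shifted_controls":
        ctrl_acc = merge_accumulators([r[2] for r in results])
        if config.coverage_norm:
            ctrl_acc = coverage_normalize(ctrl_acc)
        ctrl_pu = finalize_mean(ctrl_acc)
        normalizer = NormalizerMatrix(ctrl_pu.matrix, "shifted_controls", n_ctrl)
    else:
        normalizer = None

    if config.coverage_norm:
        obs = coverage_normalize(obs)
    metadata = {
        "resolution": genome.resolution,
        "mode": config.mode,
        "flank_bp": config.flank_bp if config.mode != "rescaled" else None,
        "target_size": config.target_size if config.mode == "rescaled" else None,
        "min_sep": config.min_sep,
        "max_sep": config.max_sep,
        "normalization": config.normalization,
        "nshifts": config.nshifts,
        "balanced": config.balanced,
        "coverage_norm": config.coverage_norm,
        "seed": config.seed,
        "drops": dict(specs.drops),
    }
    pileup = finalize_mean(obs, metadata)
    if normalizer is not None:
        pileup = apply_normalizer(pileup, normalizer)

    summary = {
        "n_windows": pileup.n_windows,
        "n_control_windows": n_ctrl,
        "drops": dict(specs.drops),
        "normalization": config.normalization,
        "central3x3": scoring.central_enrichment(pileup)
        if pileup.shape[0] >= 3
        else float("nan"),
    }
    logger.info(
        "pile-up complete: %d windows (%s dropped), normalization=%s, "
        "central 3x3 = %.4g",
        summary["n_windows"],
        summary["drops"],
        summary["normalization"],
        summary["central3x3"],
    )
    if config.out_path:
        contact_io.write_pileup_text(pileup, config.out_path)
    return pileup, summary


def run_loopability(config: RunConfig, out_tsv=None):
    """Anchored pile-ups for every region; returns the score table."""
    if not config.regions_path:
        raise ValueError("loop-ability requires a BED path")
    if config.expected_path is not None and config.nshifts is not None:
        raise ValueError("--expected and --nshifts are mutually exclusive")
    matrix = read_cool(
        config.cool_path,
        use_weights=config.balanced,
        weight_column=config.weight_column,
    )
    genome = matrix.genome
    regions = contact_io.read_regions(config.regions_path, genome)
    if config.chroms:
        regions = contact_io.RegionSet(
            regions.table[regions.table["chrom"].isin(config.chroms)], genome
        )
    if config.expected_path is not None:
        expected = contact_io.read_expected(
            config.expected_path, genome, config.expected_value_column
        )
        nshifts = None
    elif config.nshifts is not None:
        expected = None
        nshifts = config.nshifts
    else:
        expected = compute_expected(matrix, balanced=config.balanced)
        nshifts = None
    table = scoring.loopability_table(
        regions,
        matrix,
        flank_bp=config.flank_bp,
        min_sep=config.min_sep,
        max_sep=config.max_sep,
        expected=expected,
        nshifts=nshifts,
        balanced=config.balanced,
        coverage=config.coverage_norm,
        seed=config.seed,
    )
    if out_tsv:
        table.to_csv(out_tsv, sep="\t", index=False, na_rep="nan")
    return table
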