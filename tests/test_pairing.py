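"""Window enumeration: counts, edge policy, separation bands, sampling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hicpileup.contact_io import BinnedGenome, PairSet, RegionSet
from hicpileup.pairing import (
    NoUsableWindowsError,
    WindowSpec,
    anchored_pairs,
    combinations_from_regions,
    cross_pairs,
    flank_bins,
    local_windows,
    pairs_from_bedpe,
    rescaled_windows,
    subset_sample,
)


def regions_at(genome, chrom_bins):
    """RegionSet with one 1-bin region centered at each (chrom, bin)."""
    res = genome.resolution
    df = pd.DataFrame(
        [(c, b * res, (b + 1) * res) for c, b in chrom_bins],
        columns=["chrom", "start", "end"],
    )
    return RegionSet.from_frame(df, genome)


@pytest.fixture
def genome():
    return BinnedGenome(("chr1", "chr2"), (3_000_000, 3_000_000), 10_000)


def make_pairset(genome, rows):
    res = genome.resolution
    recs = [
        (c, b1 * res, (b1 + 1) * res, b2 * res, (b2 + 1) * res, b1, b2)
        for c, b1, b2 in rows
    ]
    df = pd.DataFrame(
        recs,
        columns=["chrom", "start1", "end1", "start2", "end2", "center_bin1", "center_bin2"],
    )
    return PairSet(df, genome)


def test_pairs_separation_and_window_shape(genome):
    ps = make_pairset(genome, [("chr1", 100, 140)])
    specs = pairs_from_bedpe(ps, flank_bp=200_000, genome=genome, min_sep=105_000)
    assert len(specs) == 1
    assert specs[0].shape() == (41, 41)  # 100 kb pad at 5 kb would be the same rule
    assert specs[0].separation_bins == 40


def test_flank_100kb_at_5kb_gives_41x41():
    g = BinnedGenome(("chr1",), (3_000_000,), 5_000)
    assert flank_bins(100_000, 5_000) == 20
    ps_df = pd.DataFrame(
        [("chr1", 500_000, 505_000, 900_000, 905_000, 100, 180)],
        columns=["chrom", "start1", "end1", "start2", "end2", "center_bin1", "center_bin2"],
    )
    specs = pairs_from_bedpe(PairSet(ps_df, g), flank_bp=100_000, genome=g)
    assert specs[0].shape() == (41, 41)


def test_edge_windows_dropped_counted(genome):
    ps = make_pairset(genome, [("chr1", 5, 40), ("chr1", 100, 140)])
    specs = pairs_from_bedpe(ps, flank_bp=200_000, genome=genome)
    assert len(specs) == 1
    assert specs.drops["edge"] == 1


def test_no_usable_windows_lists_reasons(genome):
    ps = make_pairset(genome, [("chr1", 100, 110)])
    with pytest.raises(NoUsableWindowsError, match="separation"):
        pairs_from_bedpe(ps, flank_bp=50_000, genome=genome, min_sep=500_000)


def test_separation_bounds_inclusive_and_match_post_filter(genome):
    rows = [("chr1", 50, 50 + k) for k in range(5, 40)]
    ps = make_pairset(genome, rows)
    min_sep, max_sep = 100_000, 250_000
    specs = pairs_from_bedpe(ps, 50_000, genome, min_sep, max_sep)
    unfiltered = pairs_from_bedpe(ps, 50_000, genome)
    manual = [
        s
        for s in unfiltered
        if min_sep <= s.separation_bins * genome.resolution <= max_sep
    ]
    assert [(s.bin_i, s.bin_j) for s in specs] == [(s.bin_i, s.bin_j) for s in manual]
    seps = {s.separation_bins * genome.resolution for s in specs}
    assert min_sep in seps and max_sep in seps  # inclusive bounds


def test_combinations_count_matches_brute_force(genome):
    rs = regions_at(genome, [("chr1", b) for b in (50, 90, 130, 170)])
    specs = combinations_from_regions(rs, flank_bp=100_000)
    assert len(specs) == 6  # C(4,2)
    rs2 = regions_at(genome, [("chr1", 50), ("chr2", 60)])
    with pytest.raises(NoUsableWindowsError):
        combinations_from_regions(rs2, flank_bp=100_000)  # no intra pairs


def test_combinations_brute_force_on_larger_instance(genome):
    rng = np.random.default_rng(0)
    bins = sorted(rng.choice(np.arange(30, 270), size=40, replace=False))
    rs = regions_at(genome, [("chr1", int(b)) for b in bins])
    specs = combinations_from_regions(rs, flank_bp=50_000, min_sep=100_000, max_sep=1_000_000)
    brute = 0
    for i in range(len(bins)):
        for j in range(i + 1, len(bins)):
            sep = abs(bins[j] - bins[i]) * 10_000
            if 100_000 <= sep <= 1_000_000:
                brute += 1
    assert len(specs) == brute
    assert all(s.in_range(genome.n_bins(s.chrom)) for s in specs)


def test_cross_pairs_counts_and_equivalence(genome):
    a = regions_at(genome, [("chr1", 60), ("chr1", 120)])
    b = regions_at(genome, [("chr1", 80), ("chr1", 160), ("chr1", 200)])
    specs = cross_pairs(a, b, flank_bp=100_000)
    assert len(specs) == 6  # 2 x 3
    # A == B reduces to unordered combinations (self-pairs excluded)
    same = regions_at(genome, [("chr1", b) for b in (50, 90, 130, 170)])
    cx = cross_pairs(same, same, flank_bp=100_000)
    cb = combinations_from_regions(same, flank_bp=100_000)
    assert {(s.chrom, s.bin_i, s.bin_j) for s in cx} == {
        (s.chrom, s.bin_i, s.bin_j) for s in cb
    }


def test_local_windows_on_diagonal_and_edges(genome):
    rs = regions_at(genome, [("chr1", 50), ("chr1", 10), ("chr2", 100)])
    specs = local_windows(rs, flank_bp=400_000)  # flank 40 bins
    assert specs.drops["edge"] == 1  # region at bin 10
    assert len(specs) == 2
    assert all(s.bin_i == s.bin_j for s in specs)
    assert specs[0].shape() == (81, 81)


def test_rescaled_window_span_arithmetic():
    g = BinnedGenome(("chr1",), (20_000_000,), 5_000)
    df = pd.DataFrame(
        [("chr1", 10_000_000, 10_600_000)], columns=["chrom", "start", "end"]
    )
    rs = RegionSet.from_frame(df, g)
    specs = rescaled_windows(rs, pad_fraction=1.0, target_size_bins=99)
    (s,) = specs
    lo, hi = s.span_i
    assert hi - lo == 360  # 120-bin domain + 120 bins padding each side
    assert s.span_i == s.span_j


def test_rescaled_mixed_sizes_same_output_shape():
    g = BinnedGenome(("chr1",), (20_000_000,), 5_000)
    df = pd.DataFrame(
        [("chr1", 5_000_000, 5_300_000), ("chr1", 10_000_000, 10_900_000)],
        columns=["chrom", "start", "end"],
    )
    specs = rescaled_windows(RegionSet.from_frame(df, g), 1.0, 99)
    assert len(specs) == 2
    assert specs[0].shape() != specs[1].shape()  # native spans differ...
    # ...but both are rescale-mode specs headed for the same 99x99 target
    assert all(s.is_rescaled for s in specs)


def test_anchored_pairs_orientation_and_counts(genome):
    rs = regions_at(
        genome, [("chr1", 150)] + [("chr1", b) for b in range(30, 280, 25)]
    )
    specs = anchored_pairs(0, rs, flank_bp=100_000, min_sep=100_000)
    assert specs  # several in-band partners
    assert all(0 in s.source_ids for s in specs)
    for s in specs:
        # anchor at bin 150: transposed iff the anchor is the downstream member
        assert s.transpose == (s.bin_j == 150)
    # anchor with no in-band partner: empty stream, not an error
    lonely = regions_at(genome, [("chr1", 150), ("chr2", 100)])
    assert list(anchored_pairs(0, lonely, flank_bp=100_000)) == []


def test_subset_sample_determinism_and_identity(genome):
    rs = regions_at(genome, [("chr1", b) for b in range(30, 270, 5)])
    specs = combinations_from_regions(rs, flank_bp=50_000)
    a = subset_sample(specs, 50, seed=9)
    b = subset_sample(specs, 50, seed=9)
    assert [(s.bin_i, s.bin_j) for s in a] == [(s.bin_i, s.bin_j) for s in b]
    full = subset_sample(specs, 10**6, seed=9)
    assert {(s.bin_i, s.bin_j) for s in full} == {(s.bin_i, s.bin_j) for s in specs}


def test_subset_sample_uniform_inclusion(genome):
    """Every window's inclusion frequency matches n/N (chi-square over seeds)."""
    rs = regions_at(genome, [("chr1", b) for b in range(40, 240, 10)])
    specs = combinations_from_regions(rs, flank_bp=50_000)
    N, n, reps = len(specs), 40, 400
    counts = np.zeros(N)
    key = {(s.bin_i, s.bin_j): k for k, s in enumerate(specs)}
    for seed in range(reps):
        for s in subset_sample(specs, n, seed=seed):
            counts[key[(s.bin_i, s.bin_j)]] += 1
    expected = reps * n / N
    chi2 = ((counts - expected) ** 2 / expected).sum()
    p = stats.chi2.sf(chi2, df=N - 1)
    assert p > 1e-4
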