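# Methods

## The pile-up procedure

Each chromosome's contact matrix is loaded once as a sparse upper-triangular
set of `(bin_i, bin_j, count)` triplets; queries reflect across the diagonal.
A window stream (from loop-anchor pairs, pairwise combinations of one region
set, two-set cross pairs, on-diagonal local windows, variable-span rescale
windows, or one anchor against its partners) is extracted window by window
and accumulated into a running per-pixel sum, a per-pixel count of finite
contributions, the window tally, and — when coverage normalization is
requested — running sums of the per-bin chromosome coverage across the row
and column flanks. Chromosomes are processed independently (optionally in
parallel), merged by field-wise summation, and finalized into the per-pixel
mean.

Two bookkeeping choices matter:

* **Per-pixel denominators.** The mean divides each pixel's sum by that
  pixel's own count of finite contributions rather than by the total window
  tally. The two coincide exactly when no bin carries an invalid balancing
  weight (asserted by a test); when invalid bins do occur, per-pixel counts
  prevent unmappable regions from dragging pixels toward zero.
* **Edge policy.** A window that would cross a chromosome end is dropped
  entirely (and counted by reason) instead of being padded with missing
  values, so every retained window contributes to every pixel.

A balanced value is `count * w_i * w_j`; a bin with a non-finite weight makes
its entire row and column missing (NaN), which distinguishes unmappable bins
from genuinely zero contact. Missing pixels are excluded from sums and from
all scores.

## Distance normalization

**Expected (default).** The per-chromosome expected profile `d[k]` is the
mean contact at separation `k`, averaged over *all* valid bin pairs at that
offset — structural zeros between valid bins count, stored-pixel-only means
would overestimate. Under the distance-only null the expected map is
Toeplitz, so an expected window for any location is filled directly from
`d[|row_bin - col_bin|]`, never materializing the chromosome matrix
(O(window²) memory). Expected windows over the *same* spec stream as the
observed pile-up (same drops) are averaged into the normalizing matrix and
the observed mean is divided by it: ratio of averages, matching the order of
operations of the accumulation itself; average-of-ratios is deliberately not
offered. When `--unbalanced` is set, the expected follows the data mode and
is computed on raw counts.

**Shifted controls.** Each window spawns `n_shifts` controls obtained by
moving both anchors by one shared offset drawn uniformly from the
in-chromosome positions at least `min_shift` bins away from the source
(default `min_shift = flank`; note a shift of exactly `flank` bins still
overlaps the source window by about half — callers wanting strictly disjoint
controls should pass `min_shift_bins >= 2*flank + 1`). Controls preserve the
anchor separation and inherit every active option — balancing, coverage
normalization, rescaling, anchored transposition — so numerator and
denominator are exchangeable. A window on a chromosome too short to place
any control contributes none and is counted. Control variance scales as
`1/(n_shifts * n_ROIs)`; small region sets need more shifts.

**Coverage normalization** (unbalanced data). The mean coverage profile of
each axis (total chromosome contacts of the bins under the flank, averaged
over windows) is scaled to unit mean and the pile-up is divided by the outer
product of the two profiles. Uniform coverage is a no-op. This is a rank-1
correction: it removes the average visibility bias of the averaged regions
(including the "sharp cross" through the central bin when anchors sit at
atypically covered sites) but cannot correct pixels whose row and column
bias are correlated — notably self-interaction pixels on the main diagonal,
whose bias is `b_i^2`. It is known to slightly over-correct the central
pixel relative to balanced data; no counter-correction is applied.

## Rescaling

Variable-size windows (domains padded by `pad_fraction` of their own length
per side) are resampled to a common odd `target_size` with area-weighted
block aggregation (conservative resampling): each output pixel is the
overlap-weighted average of the input pixels it covers. Constants are
preserved exactly, block matrices map to block averages, and results are
platform-reproducible. Missing input pixels are first imputed by the mean of
their diagonal (constant-separation line) within the window; any output
pixel drawing more than 50% of its weight from originally missing inputs is
re-masked afterwards. Coverage vectors are resampled with the same weights.

## Scores and quality control

* Dataset-level enrichment: mean of the central 3×3 pixels, missing-aware.
* Loop-ability: the *single* central pixel of each region's anchored
  pile-up (a 3×3 option exists); one row per region with its partner count,
  score, corner CVs and filter flag — regions are flagged, never silently
  dropped, and zero-partner regions get a missing score.
* Display normalization: division by the mean of the top-left and
  bottom-right corner pixels (1×1 by default; configurable). Scale-invariant
  and idempotent.
* Noise filter: the coefficient of variation (sample standard deviation /
  mean) of the 5×5 upper-left and lower-right corners; a pile-up fails when
  either CV is **0.5 or above** (boundary inclusive). The window must be at
  least 13×13 so the corners cannot touch the central 3×3. A corner more
  than half missing has undefined CV and fails conservatively. The two
  corner sizes (1×1 for display scaling, 5×5 for the noise filter) are
  intentional, not an inconsistency.

Anchored pile-ups orient every window so the anchor occupies the row axis
(windows whose anchor is the downstream member are transposed), keeping the
anchor on a fixed side of the plot.

## Window enumeration rules

Separation filters are inclusive bounds on center-to-center distance in bp
and commute with post-hoc filtering. Flanks in bp are rounded up to whole
bins (logged). A region's representative bin is `floor(midpoint/resolution)`
with BED/BEDPE taken as 0-based half-open. Self-pairs (identical center
bins) are excluded from combinations and cross mode — they are on-diagonal
and would contaminate off-diagonal averages. BEDPE rows that collapse to the
same bin pair at coarse resolution are kept (each annotation record counts
once). Anchor pairs whose intervals overlap are kept; separation filters
decide. Random subsetting draws exactly `min(n, total)` windows uniformly,
deterministically per seed. Per-chromosome random streams are derived from
the run seed and a CRC of the chromosome name, so serial and parallel runs
agree to float-summation order (< 1e-12); chromosome name matching is exact
(no silent `chr`-prefix reconciliation).

## The synthetic generator

`hicpileup.synthetic` simulates the structure the analysis assumes:

    lambda(i,j) = depth_scale * b_i * b_j * decay(|i-j|)
                  * loop_factor(i,j) * domain_factor(i,j)

with `decay(k) = diagonal_value * k^-alpha` for `k >= 1` (defaults
`alpha = 1`, `diagonal_value = 100` — a mammalian-like contact-decay slope
and a deeply sequenced map at the default depth; `depth_scale` emulates
shallower libraries), `decay(0) = 2*decay(1)` for the self-interaction
diagonal (excluded from off-diagonal analyses anyway), lognormal per-bin
biases `b_i` (σ = 0.3 emulates typical visibility variation), focal loops as
multiplicative folds on a square footprint (optionally Gaussian-blurred,
fold preserved at the center; overlapping features stack multiplicatively),
and enriched domains as folds on `[start,end)²` blocks. Counts are Poisson
draws of the upper triangle; the same seed yields a byte-identical pixel
table. Balancing weights are either exact (`w = 1/b`) or iteratively fitted
to equalize marginals (tolerance 1e-6). Fixtures are written in the
single-resolution cooler HDF5 layout (chroms/bins/pixels/indexes,
symmetric-upper storage) with an optional ground-truth JSON sidecar.

Not emulated: compartment checkerboards, trans contacts, overdispersion
beyond Poisson, restriction-fragment artefacts, and the binarized nature of
true single-cell maps (sparse depth is approximated via `depth_scale`).
Passing tests therefore demonstrate correctness of the averaging,
normalization and scoring machinery under a realistic decay-plus-features
null, not robustness to every artefact of real libraries.

## Problem sizes and study conditions in the test suite

Unit fixtures use 2 chromosomes × 300 bins. Recovery analyses use 500
planted loops (fold 3, 3×3 footprint so the central 3×3 statistic measures
the fold directly) on a 4-chromosome × 1500-bin genome — sparse enough that
the planted signal inflates the chromosome-wide expected by well under 1%;
the site sampler keeps planted footprints disjoint because overlapping
folds stack multiplicatively. The coverage-normalization analysis places
anchors at above-median-bias bins (emulating peak calls at well-covered
sites, which is what produces the central cross in real unbalanced data)
with separations above the window width so windows stay clear of the
`b_i^2` diagonal that a rank-1 correction cannot fix. The rescaled-domain
analysis plants eight domains of mixed sizes (40–180 bins, fold 2) on a
4 × 2500-bin genome — about 9% domain coverage, keeping the bias from
shifted controls landing on other domains small — and reads the fold as the
interior/exterior ratio of control-normalized sums, with the interior taken
as the middle third of the rescaled window minus the diagonal strip. The
whole suite runs in well under a minute.

## Limitations

Trans (inter-chromosomal) pile-ups, strand-aware anchor flipping, z-score
distance normalization, multi-resolution traversal beyond selecting one
resolution, and matrix balancing itself (weights are consumed, not computed)
are out of scope. Loop-ability rows are scored independently; statistical
comparison between region groups is left to downstream analysis.
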