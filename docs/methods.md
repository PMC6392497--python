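# Methods

This note documents the models, conventions and numerical choices behind
`voxatlas`, what the synthetic phantoms do and do not emulate, and the known
limitations.

## Coordinate frame and volume model

All volumes live on one shared voxel grid, indexed `[x, y, z]` with
x = left→right, y = anterior→posterior, z = dorsal→ventral. Grids are
compatible iff dimensions and spacing (µm) are equal. NIfTI affines are read
only for spacing; orientation is ignored because inputs are assumed already
co-registered (registration itself is out of scope — this package consumes
registered volumes). An affine with off-diagonal terms triggers a warning,
not an error.

`value_kind` tags each volume's semantics: `raw` acquisition intensities,
`normalized8` (0–255), `binary` occupancy, or integer `label`. Averaging is
computed in float64 and warns (does not fail) below three input scans, the
atlas policy for representative line images.

## Intensity normalization

`normalize_to_8bit` saturates the brightest `saturation_fraction` of voxels
(default 1e-4, i.e. the top 0.01%): the reference is the
`1 − saturation_fraction` quantile (linear interpolation) of either all
voxels (default) or only mask voxels — exposed because the choice of domain
is a genuine free parameter; all-voxel quantiles keep the default
reproducible without a mask. Values are clipped at the quantile, scaled to
255 and rounded half-to-even, then stored as uint8. An all-zero volume maps
to zeros rather than dividing by a zero quantile.

## Spatial-search index

Per line: binarize at the line's cellular threshold (super-threshold means
`>=`, consistently everywhere), then max-pool downsample by 4 per axis.
Max-pooling guarantees no false negatives: any set full-resolution voxel
inside a query box sets its downsampled cell. Edge cells pool the truncated
remainder.

Packing layout (fixed so fragment files are bit-exact across
implementations): cells linearized x-fastest then y then z; bit `i` of byte
`j` holds linear cell `8j + i`, least-significant bit first. An 8×8×8 block
is therefore exactly 64 bytes — an 8× reduction over byte-per-voxel
storage. The downsampled grid is zero-padded to multiples of 8; for each
block coordinate the per-line payloads are concatenated in registry order
into one fragment of `64 × n_lines` bytes (16,896 bytes ≈ 17 kB at 264
lines). Fragments are stored one file per block plus a JSON manifest
carrying line order, factor and dimensions.

Queries convert the full-resolution box to downsampled coordinates with
outward (cover) rounding, preserving the no-false-negative property, and
touch only overlapping fragments. `min_cells` (default 1) is the only query
threshold; a fraction-of-box criterion is deliberately not implemented. A
brute-force triple-loop search over the same converted box is kept as an
independent oracle and is cross-checked against the packed path over
hundreds of randomized queries in the tests.

## Intersection prediction

Default mode is the voxel-wise minimum of the two normalized volumes:
continuous, symmetric, dominated by both inputs, and robust to the two lines
having different thresholds. `binary_and` (AND of the two thresholded masks)
is provided for mask-style overlap predictions. Predicted overlap is an
upper bound on realized co-expression — intermingled cell types within a
voxel cannot be separated by co-registered volumes, so predictions require
experimental verification. Depth-coded projections color each ray by the
depth of its first maximum (ties broken toward the viewer) scaled by the
maximum intensity.

## Coverage statistics

The cell-body (cellular) volume is defined by the marker ratio
`soma / (soma + neuropil) >= ratio_threshold` inside the brain mask, with
both-zero voxels excluded. The threshold default 0.5 ("soma marker
dominates") is a parameter because no principled value exists; it is
surfaced in the config. A line's coverage is the fraction of cellular voxels
at or above its threshold; lines flagged as extremely broad
(`exclude_from_coverage`) are dropped from library statistics. The library
summary reports union coverage (fraction of cellular voxels hit by ≥ 1
line), mean lines per voxel, the per-line coverage distribution, and a
50-bin histogram on [0, max] (binning is a presentation choice). Coverage
converts to approximate neuron counts by multiplying by the brain-wide
mature-neuron total (default 92,000 at 6 dpf) and rounding to two
significant figures.

## Expression binning

Cubic bins (default edge 20 µm, which must be commensurate with the voxel
spacing) tile the left hemisphere anchored at the grid origin; a bin is kept
iff fully inside the brain mask and left of the midline plane (default
`nx/2`, a parameter since atlas frames are assumed left-right centered). The
bin count is therefore data- and anchor-dependent. Each bin pools its
mirror-image box across the midline unconditionally (clipped to the grid if
the reflection protrudes); per-line vectors are rescaled by their maximum,
so values are comparable across bins *within* a line but never between
lines. Region means over integer label volumes follow the same within-line
0–1 scaling; labels with no voxels are reported as missing, not zero.

## Stratified neuron-count estimation

Brain voxels are stratified into `n_bins` (default 5) equal-population
quantile bins of the soma:synapse ratio `r = soma/(soma + synapse)` (0 where
both are zero). Quantile edges use linear interpolation; voxels are assigned
by counting edges strictly below their value, so a constant field falls
entirely into the first bin. Equal-population cuts (rather than equal-width
or manual) make every stratum large enough to sample; the rule is a
documented choice, not a fitted one.

Sampling volumes (default five 30 µm cubes per bin) are placed
reproducibly: all anchors whose box has plurality label equal to the target
bin are enumerated via integral images, visited in a seeded uniform-random
order, scarcest bin first, keeping non-overlapping boxes; if a draw wedges,
the placement restarts with a derived seed. Neuron counting inside a box is
*input* to the estimator (manual or external counting), not part of it;
the synthetic module supplies Poisson ground-truth counts.

The estimator is `total = V · Σ_b f_b · mean(counts_b) / v_box` with `V` the
brain volume, `f_b` the voxel fraction of bin b and `v_box` the box volume.
It is linear in counts and unbiased under Poisson sampling. The standard
error treats bins as independent:
`se² = V² · Σ_b f_b² · sem_b² / v_box²` with `sem_b` the standard error of
the mean box count. With five boxes per bin, `sem_b` is itself noisy, so the
±2·se interval covers the truth slightly below the nominal 95% (≈ 90–93% in
the Monte-Carlo checks) — a small-sample effect of estimating the variance
from five boxes, inherent to the design.

## Pool design and integration-site deconvolution

Lines are assigned distinct unordered pool pairs (capacity `C(n_pools, 2)`),
greedily taking the least-loaded unused pair (smallest load sum, then
smallest maximum) with seeded tie-breaking; pool sizes balance to within one
line. Sites present in every pool (count ≥ 1 by default) are off-target
capture and removed first; the filter is idempotent. Nearby sites on one
chromosome (gap ≤ 100 bp, configurable) are merged to absorb alignment
scatter, summing counts at the first position; coordinates are 0-based and
strand is ignored for site identity.

"High and specific enrichment" is operationalized as: count ≥ `min_reads`
(default 10) in *both* pools of exactly one line's pair and
≤ `max_bg_reads` (default 2) in every other pool. Sites whose
above-background pools match no pair are rejected as
`no_matching_signature`; sites compatible with a pair's background profile
but failing the enrichment bar are `below_enrichment`. Assignment is
monotone in `min_reads`. A fold-change rule was deliberately not added to
keep the behavior auditable.

The simulation harness plants one site per line with ~Poisson(50) reads in
its pair, Poisson(0.1) background everywhere, and optional all-pool
off-target sites — a realistic enrichment-to-background regime for pooled
amplicon sequencing. Under these conditions deconvolution achieves
precision 1.0 and recall > 0.99 in the Monte-Carlo checks.

## Synthetic phantoms

`make_phantom_brain` builds an ellipsoidal brain mask with complementary
soma (shell-trending) and neuropil (core-trending) channels plus smooth
seeded regional texture, so the ratio-based cellular mask and density strata
have realistic blob-like geometry (purely radial profiles would make the
extreme strata thin shells that cannot host cubic sampling volumes). With
the symmetry flag the volumes equal their x-mirror exactly. The default grid
is 128×64×64 voxels at 2 µm isotropic — large enough for 20 µm bins, 30 µm
sample boxes and 8×8×8 index blocks to be non-degenerate, small enough for
seconds-scale tests; the test suite also uses a 64×32×32 variant.

What the phantoms do *not* emulate: microscope noise, registration error,
intensity inhomogeneity, biological variability between animals, or
realistic expression-pattern shapes. Passing tests therefore validate the
*computations* themselves (packing, search, estimators, deconvolution), not
the biological accuracy of any particular atlas's numbers;
published collection-level figures (line counts by category and mapping
status) are shipped as a census table, and desk-scale runs make no claim to
reproduce image-derived statistics such as median coverage percentages.

## Problem sizes and defaults

Tests and the acceptance script use the phantom grids above, 20 lines × 500
random boxes for search cross-checks, 200 Monte-Carlo replicates for the
stratified estimator, and 20 simulation seeds × 50 lines for pool
deconvolution — sizes chosen to make the statistical checks stable at
seconds-scale runtime. All defaults (saturation 1e-4, downsample 4, block
edge 8, bin edge 20 µm, 5 density bins, 5 × 30 µm boxes, 92,000 total
neurons, pool thresholds 10/2, 100 bp merge window) live in
`voxatlas.config.Config` and are overridable per call or via a YAML config;
CLI outputs carry a provenance header with the package version, config hash
and seeds.
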