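# Methods

## Overview

`mitonetquant` quantifies mitochondrial network morphology in single-channel
fluorescence micrographs of cells expressing an outer-membrane reporter
(e.g. a TOMM-20::GFP fusion). Starting from a per-cell region of interest it
produces one row of network attributes: mitochondrial coverage, object count
and density, mean object length and area, and network complexity (junction
points per network). The pipeline is

    crop -> enhance (CLAHE, median, unsharp) -> binarize (Otsu + mask
    regularization + speck removal) -> skeletonize -> tag/label ->
    branch graph -> per-object measurement -> per-cell row -> CSV

Everything downstream of the crop is a pure function of the pixel raster and
the parameter set, so batches reproduce byte-identical CSVs.

## Enhancement and binarization

Local contrast is enhanced by contrast-limited adaptive histogram
equalization (CLAHE) on a `clahe_tiles x clahe_tiles` grid (default 8) with
clip limit `clahe_clip` (default 0.01), after rescaling the raster to its
own min/max (CLAHE operates on the occupied dynamic range). A median filter
over a disk of radius `median_radius_px` (default 1 px) suppresses impulse
noise, and an unsharp mask `out = in + amount * (in - Gaussian(in, radius))`
(default radius 2 px, amount 0.6) restores tubule edge contrast. A flat
image passes through unchanged; images smaller than the tile grid fall back
to global histogram equalization with a warning.

The default threshold is Otsu's method computed per ROI by exhaustive search
over all occupied intensity levels; the reported threshold is the smallest
foreground intensity (mask is `pixels >= threshold`). A fixed threshold is
available for calibrated acquisitions. Two mask-level clean-ups follow:

* **3x3 majority regularization** (`smooth_mask`, default on). A foreground
  pixel survives if at least 5 of its 3x3 neighbourhood are foreground.
  Pixel-scale boundary roughness on noisy images otherwise produces short
  skeleton spurs, each of which manufactures a spurious junction — on
  moderately noisy synthetic frames this inflated junction counts by ~90%.
  The majority vote removes single-pixel roughness without eroding tubules
  of width >= 3 px (binary opening, tested as an alternative, splits
  tubules at noise-pinched necks). No skeleton-level spur pruning is
  performed.
* **Speck removal**: 8-connected components smaller than `min_object_px`
  (default 4) are dropped.

These defaults are this package's own calibration; the appropriate values
depend on magnification and noise level and are all exposed in the config.

A known, quantified bias: any global threshold at the Otsu level
(~0.3 x amplitude above background) includes part of the point-spread
blur skirt, widening a 3 px tube to ~3.8 px. Measured coverage therefore
overestimates true tubule coverage by roughly a quarter of its value
(relative). At the sparse coverages this package targets by default (~5%)
that is ~1.3 percentage points absolute; for densely covered cells (e.g.
muscle at 20-40% coverage) the absolute bias scales proportionally and
coverage should be read as a consistent relative measure, not an absolute
one.

## Skeletonization and the branch graph

The binary mask is thinned to a unit-width, 8-connected skeleton by
iterative morphological thinning. Two refinements make the result a true
contract:

* **Orientation canonicalization.** Directional thinning passes are not
  equivariant under rotation. The mask is transformed to the
  lexicographically smallest of its eight dihedral (rotation/mirror)
  variants, thinned there, and transformed back — so every count and length
  is exactly invariant under 90-degree rotations and flips of the input.
* **Thick-block reduction.** Residual fully foreground 2x2 blocks at dense
  crossings are reduced by deleting simple points (pixels whose removal
  preserves local connectivity). A block in which all four pixels are
  essential (each deletion would disconnect crossing arms) is irreducible;
  it is kept and its pixels merge into a single junction node.

Each skeleton pixel is tagged by its 8-neighbour count: endpoint (<= 1),
slab (2), junction (>= 3); an isolated pixel is a degenerate single-pixel
object tagged as an endpoint. Connected skeleton components are labelled
1..K in raster-scan order, which fixes all downstream orderings.

The graph stage merges 8-connected junction pixels into single junction
nodes (otherwise one biological crossing counts as 2-4 junctions, a
thinning artifact), takes endpoints as nodes, and traces branches from node
pixels through slab pixels. Branch path length uses the standard step
metric — `pixel_size_um` per orthogonal step, `sqrt(2) * pixel_size_um` per
diagonal step — plus the Euclidean distance from each terminal path pixel
to the incident node's centroid. The centroid extension is the length
convention implied by junction merging: a branch leaving a merged cluster
begins at the cluster's geometric centre, not its rim, and it reproduces
the closed-form arm length of a symmetric cross exactly. A closed curve
containing no node becomes one anchor node with a single self-edge: one
object, zero endpoints, zero junctions.

## Per-cell attributes

Per object (one labelled skeleton component): total skeleton length (sum of
branch lengths; a `longest-branch` mode is available), area of the
8-connected mask component containing the skeleton, branch / junction /
endpoint counts, and the network flag (>= 1 merged junction node). Per cell:
coverage (% of valid ROI pixels that are foreground — polygon ROIs count
only their interior), object count, objects per 100 um^2 (the
object-density normalization unit, stated in the CSV header), means of
object length and area, network count, total junctions, mean junctions per
network, and total branches. Cells with no objects report means as missing
values (empty CSV fields), never zero. Doubling the pixel size exactly
doubles lengths and quadruples areas while leaving counts and coverage
unchanged.

Every row carries a fingerprint of the full parameter set (preprocessing
parameters, length mode, pixel size, package version); the CSV writer
refuses to mix fingerprints unless explicitly overridden, enforcing
constant-parameter batches mechanically.

## Synthetic ground truth

The generator emulates the reporter signal with known truth. Tubule
centerlines are smoothed random walks: unit (1 px) steps with turning angle
bounded at 30 degrees, avoiding both other objects and their own earlier
path by `min_separation_px` (so no unrecorded self-crossings occur). Side
branches spawn at interior anchor points (every 10 steps) with probability
`branching_prob`, creating recorded degree-3 junctions. Centerlines are
rasterized at `tube_width_px`, blurred with a Gaussian PSF, and corrupted
by Poisson shot noise plus Gaussian read noise. SNR is defined as (peak
tubule intensity - background) / noise sd at background, where the peak
accounts for PSF attenuation of the tube profile.

Defaults: 256 px frames at 0.1 um/px (a 25.6 um field), 12 objects of
8 +/- 2 um, branching probability 0.25, 3 px (~0.3 um) tube width, PSF
sigma 1 px, background 20, foreground 60, read noise sd 3, Poisson gain 1
(SNR ~6.4), separation 5 px — a sparse (~5% coverage), moderately branched
network as in neuronal cells under moderately noisy high-NA acquisition.
Each object draws from an RNG substream keyed by (seed, object index,
attempt), so adding an object never perturbs earlier ones and frames are
bit-reproducible from the seed.

Because the self-separation constraint truncates long walks (a bounded-turn
walk eventually traps itself at ~100-150 steps), the requested length
distribution is an upper bound; the recorded truth always reflects realized
polylines. Condition generators therefore calibrate on realized renders:
`simulate_condition_pair` produces a fused member (10 long, branched
objects; best-effort calibration toward 5.5% coverage) and a fragmented
member (50 short, unbranched objects) re-rendered until its true coverage
matches the fused member within 5% relative. `fragmentation_sweep` renders
5/10/20/40/80 objects at a shared total length (default 70 um),
calibrating each level to the first level's realized coverage.

What the generator does not model: autofluorescence, structured background
(e.g. muscle striations), out-of-focus light beyond a single Gaussian PSF,
variable tube width, and genuinely overlapping mitochondria. Passing
recovery tests therefore demonstrate correctness of the measurement chain
on idealized tubular signal, not segmentation robustness on every real
tissue background.

## Validation problem sizes

The test suite validates recovery on 100 seeded default frames (object
count exact in >= 95 frames, aggregate junction error within 10%, per-frame
coverage within 2 percentage points of truth), phenotype direction on 20
fused/fragmented pairs at SNR 5 (object density and mean length must order
correctly in every pair; network count and junctions-per-network in at
least 18), and a noiseless five-level fragmentation sweep (perfect Spearman
ordering). Oracle equivalence is checked exactly against brute-force
reimplementations on 200 random small skeletons, and closed-form fixtures
(cross, H, diagonal, annulus) are asserted exactly. `scripts/acceptance.py`
recomputes the same statistics from any seed.

## Known limitations

* Coverage carries the threshold-level blur-skirt bias described above.
* Junction counts on noisy real images depend on mask regularization; with
  `smooth_mask` off they can be substantially inflated by boundary spurs.
* Only 2D planes are analysed; axially overlapping tubules merge.
* The ImageJ `.roi` reader covers rectangle and polygon records only.
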