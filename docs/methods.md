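# Methods

This note records the models, numerical choices and open design decisions
behind `mmmp`, and what the synthetic phantom does and does not establish
about real data.

## The phantom: what it emulates

A phantom stands in for one tissue section imaged over repeated staining
cycles.  Its ground truth is a labeled feature map painted from parametric
geometry primitives inside an elliptical "tissue" region: a space-filling
extracellular-matrix field, muscle bands at fixed fractional heights,
epithelial blobs (unions of jittered disks), vessel rings with background
lumina, and small nuclear disks.  Every imaging channel is rendered as
`signature[feature, channel] + N(0, noise_sd)`, rounded and clipped to the
8-bit range.

Defaults mirror the full study design: 15 IF cycles (one Cy5 antibody
each, DAPI imaged in every cycle) plus 4 brightfield histochemistry cycles
(H&E, Alcian blue, PAS, Verhoeff's), a 0–255 intensity scale, `noise_sd`
5, 100×100 px tiles at 10 % nominal overlap with 2 px Gaussian stage
jitter, and per-cycle rigid drift bounded by 6 px / 1.5°.  Brightfield
channels are generated with the stain signal bright ("negated"
orientation) and converted to conventional bright-background RGB in the
acquired stack, so the pipeline's negation step is genuinely exercised.
Brightfield signatures are the sum of a feature-dependent *tissue density*
term shared by all stains — consecutive histochemical stains of one
section show the same gross morphology — plus stain-specific highlights.
Without the shared term, cross-stain registration is nearly
rotation-ambiguous (only the tissue outline is common), which is not how
real serial stains behave.

All randomness flows through the single spec seed; equal seeds give
bit-identical datasets.  What the phantom does **not** model:
photorealistic texture, uneven illumination, bleaching chemistry,
autofluorescence, spectral spillover, or non-rigid tissue deformation.
Passing tests therefore demonstrate the correctness of the algorithms
under additive Gaussian noise and rigid geometry, not robustness to those
real-world effects.

## Stitching

Pairwise offsets between grid-adjacent tiles are estimated by normalized
cross-correlation (`skimage.feature.match_template`) of the leading block
of one tile against its neighbor, with the along-grid offset restricted to
the step implied by the overlap prior ± a 12 px window and the cross-grid
offset to ± the window.  A genuine match between tiles cut from one
acquisition scores ≈ 1; when the jittered overlap shrinks to almost
nothing the peak is weak, so pairs scoring below 0.5 fall back to the
nominal grid step and enter the global reconciliation with weight 0.01
(instead of 1), keeping the grid graph connected without letting an
unreliable pair distort the solution.  Tile positions solve a weighted
least-squares system over the pair constraints, anchored at the first
tile; overlapping pixels blend with separable triangular (feather)
weights.

The three-run consensus follows the published protocol: overlap priors of
5, 8 and 10 %, per-tile coordinate-wise median as the consensus, and the
run with the smallest summed Euclidean distance to it selected, ties going
to the smallest prior.  The prior's unit is percent of the tile edge (the
FIJI stitching convention); callers using pixels can pass
`100 * px / tile`.  Cropping is centered (2300 px default) and pads
symmetrically with the background value when the canvas is smaller.
Core-grid tracking estimates one translation per cycle — difference of
centroid means refined once from nearest-neighbor matches trimmed at half
the minimum inter-core spacing — then matches cores to reference
centroids, reporting unmatched and missing cores as dropped and raising on
ambiguous (many-to-one) matches.

## Registration

Fiducials: min–max-rescaled DAPI for IF cycles; min–max-rescaled luminance
(channel mean) of the negated RGB for brightfield cycles.  The choice of
luminance (rather than joint three-channel matching) is a documented
simplification.  A rigid transform is fit per pair by scanning rotation
about the image center on a coarse 0.5° grid over ±3°, then successive 5×
refinements down to 0.02°; at each angle the translation comes from
subpixel phase correlation (upsampling factor 20) and the candidate is
scored by NCC over non-extrapolated pixels.  Transforms are stored as
homogeneous matrices, so chaining (IF cycles to the first IF frame,
brightfield cycles among themselves, first brightfield bridged to the last
IF) is exact matrix composition.  Intensities are resampled bilinearly
(nearest-neighbor for label images); validity masks mark pixels whose
inverse map stays inside the source canvas.  A pair whose similarity falls
below 0.3 aborts the series with the offending cycle pair named.  The
final non-rigid refinement used in the original protocol is deliberately
out of scope: rigid recovery on near-rigid drift is within 0.5 px / 0.2°,
and an affine stage would be a no-op on such data, so none is shipped.

## Matrix extraction

Foreground is the intersection of all validity masks, optionally
restricted to pixels where at least one channel (brightfield negated
first) exceeds `tissue_threshold` on the normalized 0–1 scale; the default
0 keeps the presence-across-cycles rule only.  Rows follow raster order;
columns follow the panel: DAPI from the first and last IF cycles, one Cy5
column per IF cycle, R/G/B per brightfield cycle — 29 columns for the
default design.  Intensities stay on the native 8-bit scale (brightfield
stored negated); standardization is deferred to the analyses that need it.

## Unsupervised profiling

*PCA* standardizes channels to zero mean and unit variance (constant
channels dropped with a warning) and reports loadings, variance fractions
and min–max-scaled per-component score images.

*k-means* is the Hartigan–Wong transfer algorithm on raw intensities, as
in the reference protocol (k = 100, 20 passes, one start): points move
individually when `n_b/(n_b+1)·d_b² < n_a/(n_a−1)·d_a²`, with running
centroid updates (numba-compiled).  Initial centroids are k distinct rows
drawn under the given seed; empty initial clusters steal one point from a
multi-member cluster.  After the transfer passes a short Lloyd polish runs
to a fixed point so the returned model satisfies the nearest-centroid
invariant exactly; `restarts` returns the lowest-WSS start.  Like the R
routine it mirrors, quality depends on the random start — the test suite
checks equality with an exhaustive-partition oracle on a toy set, exact
recovery of noiseless phantom signatures under centroid seeding, and a
WSS no worse than Lloyd's from the identical start.

*Color mapping* embeds the k centroids in 3-D with Kruskal's nonmetric MDS
(`sklearn.manifold.MDS`, `metric=False`, normalized stress-1), initialized
from classical (Torgerson) scaling computed in-package — the same
initialization R's `isoMDS` uses, which also makes the embedding of
intrinsically 3-D centroids exact (stress ≈ 0).  Exact duplicate centroids
are collapsed before embedding and share one point, so identical profiles
always receive identical colors.  Orientation is made deterministic by
ordering axes by decreasing variance and forcing positive skew per axis;
coordinates then map to RGB with a **single shared scale** (the longest
axis spans 0–255).  Per-axis scaling would use the color cube more fully
but distorts distance ranks; the shared scale preserves the rank order of
pairwise distances exactly, which is the point of a similarity-based code.
Colors are kept as floats in [0, 255] and quantized only when an image is
rendered.

*Imputation r²* is the squared Pearson correlation, per channel, between
original intensities and each pixel's centroid value; channels with zero
variance in either vector are reported as undefined and excluded from the
mean.

*Global compilation* concatenates per-sample centroid matrices into one
(sample, cluster)-indexed table, hierarchically clusters rows
(average linkage, Euclidean — the protocol names neither, these are the
common defaults), and refits one MDS palette on the pooled centroids so
every sample can be recolored consistently.  Both steps are quadratic in
the pooled row count (the nonmetric MDS far worse), so they are skippable
flags; the 102-sample acceptance run checks the 10,200-row pooled matrix
itself on 24×24 px phantoms, a size chosen so that each of the 102
clusterings is still a real k = 100 fit.

## Automated histology

The checkerboard partition assigns pixel (r, c) to region
`1 + (⌊r/g⌋ + ⌊c/g⌋) mod 2` and selects the largest g from {100, 50, 20}
for which both regions contain every annotated category.  LDA uses class
means, a pooled within-class covariance with a relative ridge
(`1e-4 · trace/d` on the diagonal — the pixel counts dwarf the channel
count so the ridge only guards degenerate synthetic inputs), and empirical
priors (a uniform-priors flag exists; the protocol does not say which was
used).  Channels enter LDA raw, matching the k-means choice.  Training on
region 1 predicts region 2 and vice versa; the merged predictions cover
every foreground pixel, while the confusion matrix and per-feature
accuracies (diagonal over row sum, in %) count annotated pixels only.
Ablations rerun the identical procedure on a channel subset (`he` preset =
the H&E cycle's RGB columns).  Cross-sample application of a trained model
requires an identical channel layout and yields predictions without
accuracies.  Per-feature profiling runs k-means within each category
(k reduced to the distinct-row count when a category is small) and flags a
centroid feature-specific when its nearest neighbor among all centroids
shares its category.  Note that for two categories with *identical*
intensity distributions specificity collapses far below 50 %: centroids
within one set repel each other (quantizer spacing) while the other set's
positions are uncorrelated, so the nearest neighbor is usually cross-set.

## Nuclei segmentation

Global Otsu threshold on DAPI, hole filling, Euclidean distance transform,
watershed from distance peaks (minimum peak separation 5 px) to declump
touching nuclei, then an object-area gate.  Area defaults (30–5000 px)
suit ~0.3 µm/px imaging; phantom tests use smaller gates matching their
nucleus radii.  The agreement statistic between two nuclei masks is
100·|A∩B|/min(|A|,|B|) — symmetric, 100 for nested masks, undefined (NaN)
when the smaller mask is empty.

## Problem sizes and determinism

Tests and the acceptance script run phantoms between 24×24 and 280×280 px
with 5–19 cycles; these sizes make every stage's contract checkable in
seconds while leaving the algorithms identical to what larger canvases
would use.  Every stochastic component (phantom rendering, jitter, drift
draws, k-means starts, MDS) is driven by explicit integer seeds;
segmentation and registration are deterministic given their inputs.

## Known limitations

Rigid-only registration (no elastic refinement); luminance-based
brightfield matching; no illumination/flat-field correction, no
autofluorescence or spillover compensation; k is fixed by the user (no
model selection); LDA uses intensities only — no morphological or
contextual features; the global MDS palette is quadratic in the pooled
centroid count.
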