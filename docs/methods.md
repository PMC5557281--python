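# Methods

This note records the models, conventions and numerical choices behind
`ttrack`, and what the synthetic benchmark does and does not establish.

## Conventions

Coordinates are 0-based `(row, col)` with row 0 at the top; centroids are
real-valued with pixel centers at integers. Frames are 8- or 16-bit
grayscale (16-bit default; observed intensity statistics in the source
imagery reach 65535). Phases of one time point are assumed pixel-registered;
no registration is performed. Metadata CSVs are comma-separated, UTF-8,
"." decimal, header always present, floats printed at full `repr` precision
so files re-parse exactly. "Circumference" in per-cell metadata is the same
quantity as perimeter.

## Enhancement

The stretch maps the `[p, 1−p]` quantile band (default p = 0.01) linearly
onto the full bit range, clipping both tails, with quantiles computed as
order statistics with linear interpolation. The mapping is monotone
non-decreasing by construction. Constant or otherwise degenerate frames
(`hi == lo`) pass through unchanged with a warning rather than an error, so
one blank time point cannot abort a batch. Enhancement is per frame, never
per sequence. Caveat: on a nearly empty field (cells ≪ 1% of pixels) the 1%
rule saturates the cells themselves and amplifies background noise across
the whole range; detection quality then depends on the frame-derived
threshold bounds below.

## Tiled constrained thresholding

The per-tile threshold maximizes between-class variance over the tile's
*observed* unique values; cuts are evaluated between consecutive observed
values and the reported threshold is the midpoint of the best cut (smallest
cut on ties), so it lies strictly between the two classes and is meaningful
for clean two-valued tiles. The mask is `pixels > threshold`. Single-valued
tiles are cell-free by construction.

The threshold constraint band realizes the idea that a tile whose computed
threshold is implausibly low (or high) cannot contain a cell. Two modes:

- fixed bounds, default (0.08, 0.95) of the normalized range — appropriate
  for raw-scale imagery whose background sits low in the bit range;
- `threshold_bounds=None` — the lower bound is derived from the frame as
  (5th intensity percentile + 3 × 1.4826 × MAD of per-tile median
  residuals) / range. The 5th percentile sits on the dimmest background
  (cells cover a small area fraction); the per-tile residual MAD estimates
  the *noise* scale while ignoring smooth illumination gradients. This is
  the default inside the orchestrated pipeline, where enhancement has moved
  the background up the range and a fixed band would be wrong.

Components are 8-connected. The area window (default [75, 450] px, the
observed min/max cell footprint in the source imagery) is applied per
component. Note the window slightly clips the largest simulated cells
(radius 12 → area ≈ 452), which costs the detector a small, known amount of
recall at the top of the size range.

## Circle seeding

Bright round cells are additionally sought by a circular Hough transform
(radii 4–16 px by default) over Canny edges (σ = 2), with the accumulator
normalized so a response of 1 means the full circumference is supported by
edges. Seeds below a response floor of 0.4 are dropped; survivors are
non-maximum suppressed to a pairwise spacing of r_min. A seed whose centre
falls inside an existing component is absorbed; an unabsorbed seed spawns a
detection from a local threshold in a (2r+2)² window, subject to the same
area window and pixel-disjointness.

## Boundary resolution

A detection (or sub-threshold fragment) whose bounding box comes within
`boundary_margin` (2 px) of an interior tile edge triggers a tile-sized
window centred on that edge at the trigger's centroid; near a tile corner a
window centred on the corner itself is added, because a quadrant fragment's
centroid is offset from the cell centre and either edge-centred window can
clip a large cell. Windows are re-thresholded and re-extracted; window
components pressed against a window border are discarded as clipped views
(unless the border is the frame border), first-pass detections overlapping a
retained window component are replaced by it, and the final set is made
pixel-disjoint greedily, larger components first. Fragments — components
with area ≥ max(9, min_area/4) but below the area floor — act only as
triggers: a cell split by a tile edge can leave two fragments that would
otherwise never flag the edge.

## Features

Axis lengths and eccentricity come from the eigenvalues of the coordinate
covariance of the pixel set plus 1/12 on the diagonal (the variance of a
unit pixel), axes = 4√λ. This is the classic regionprops convention; it
keeps eccentricity strictly below 1 for single-pixel-wide regions and makes
a lone pixel a tiny circle. The alternative reading of "longest and shortest
distance across the cell" (Feret diameters) was rejected as less stable on
digital shapes. Perimeter is the weighted
boundary-step measure of `skimage.measure.perimeter` (orthogonal 1,
diagonal √2, corner (1+√2)/2), which is within a few percent of 2πr on
digital disks of radius ≥ 5. Intensity statistics are computed on the frame
that was segmented (normally the enhanced frame); pass the raw frame to
`compute_region_features` to measure raw intensities instead.

## Filtering

Criteria are declarative closed intervals per feature — a reproducible
stand-in for interactive expert judgement. The optional calcium-activity
floor defaults to background mode + 3 × 1.4826 × MAD (a robust 3σ rule).
Erasure resets exactly the discarded pixel sets to a background value
(default: the frame's modal intensity) on a copy of the frame and is
idempotent.

## Tracking

The link objective is made precise as: maximum-cardinality matching over
gate-admissible pairs, minimum total cost among those (solved with a
rectangular assignment solver and a large uniform penalty for inadmissible
pairs). Cost = centroid distance (px) + Σ weights · |Δx|/max(xᵢ, xⱼ) for
area, mean intensity and major axis (weights 1, 1, 0.5). The symmetric
max-normalization keeps each feature term dimensionless in [0, 1). There is
no motion model: stationary cells are handled by the zero-distance cost
minimum, as positions rather than predicted positions are matched. Track
maintenance matches live (gap-0) tracks first, then coasting tracks in
increasing gap order with the gate enlarged proportionally to the gap, so a
dying track can never displace a live one. Defaults: gate 20 px (the largest
observed per-step displacement in the source data), max 2 missed frames.

## Synthetic scenes

The generator emulates what the pipeline must survive: round (optionally
eccentric) cells of radius 5–12 px rendered as anti-aliased disks (1 px
smoothed rim) at contrast 10 000 over background 4 000 with additive
Gaussian noise σ = 1 000 (contrast/noise = 10), on 512×512 16-bit frames;
Brownian motion (σ = 1.5 px/frame/axis) plus optional global drift; an
optional linear illumination ramp specified as a fraction of cell contrast;
whole-cell multiplicative flashes (probability 0.02/cell/frame, gain 2.0)
standing in for calcium-indicator transients; and scripted entries/exits
crossing the field boundary at 8 px/frame. Initial centres are
rejection-sampled to pairwise separation ≥ 2 × max radius; scripted entry
points are kept ≥ 4 × max radius apart, entering cells stop drifting once
well inside, and exiting cells are drawn from those starting ≥ 80 px from
the edges — otherwise Brownian motion can pre-empt the scripted, sharply
timed crossing. Visibility is defined as the centre lying inside the frame.

Not simulated: optics (point-spread function, phase-contrast halos),
photobleaching, cell division or contact dynamics, subcellular calcium
microdomains. A green test on these scenes establishes that the algorithmic
contracts hold (thresholding, deduplication, assignment optimality,
recovery rates under stated noise and illumination); it does not establish
performance on real phase-contrast imagery.

## Orchestration

The pipeline layer (`ttrack.pipeline`) is a library API rather than a
command-line tool: `simulate` and `run_pipeline` accept one `PipelineConfig`
(constructible from YAML with unknown keys rejected), write per-stage
artifacts (TIFF, CSV, PNG) plus a manifest of config + seed + version, and
are driven by the scripts in `examples/`. Stages must form a prefix of
enhance → segment → filter → track → summarize because each consumes its
predecessor's output. All randomness flows from the scene seed through
`numpy.random.SeedSequence` children (one stream for dynamics, one for
rendering), so identical configs reproduce identical bytes.

## Known limitations

- Touching cells are not split (no watershed); transient merges during
  crossings briefly fragment the affected tracks.
- The area window's fixed upper bound clips the very largest cells.
- The frame-derived threshold bound assumes cells occupy a minority of the
  field; dense monolayers would need explicit bounds.
- Under a strong illumination ramp the bright-side background can clear the
  threshold constraint, costing precision (recall is preserved); the
  filtering stage is the intended remedy.
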