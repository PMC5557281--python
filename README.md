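# ttrack

Segmentation, feature extraction and tracking of T cells in time-lapse
microscopy, with a synthetic ground-truth scene generator.

## The problem

Migrating T cells imaged by phase-contrast microscopy, often together with a
genetically encoded calcium indicator (GCaMP-family), produce long image
sequences in which hundreds of small, round, low-contrast cells move, change
shape, flash brightly when calcium-release-activated calcium (CRAC) channels
open, and enter or leave the field of view. Quantifying motility and channel
activation requires detecting every cell in every frame, measuring its
morphology and intensity, discarding debris, and linking detections across
frames into identity-preserving tracks. `ttrack` implements that pipeline as
a tested Python library for image analysts and quantitative immunologists,
and pairs it with a simulator that renders scenes with exact ground truth so
every stage can be verified without real imagery.

## The method

1. **Enhancement** — each frame is contrast-stretched so a fraction
   *p* = 0.01 of pixels saturates at each end: with `lo`/`hi` the *p* and
   1−*p* intensity quantiles, output = clip((x − lo)/(hi − lo)) × (2ᵇ − 1).
2. **Detection** — the frame is partitioned into 32×32 px tiles (slightly
   larger than a cell). Each tile is binarized at its own threshold *t*\*
   maximizing the between-class variance σ²_b(t) = ω₀ω₁(μ₀ − μ₁)² (Otsu's
   criterion) over the tile's histogram; tiles whose normalized threshold
   falls outside a configurable band [t_min, t_max] are declared cell-free,
   which keeps empty background tiles from contributing noise and lets the
   per-tile thresholds absorb uneven illumination. 8-connected components
   within an area window (default [75, 450] px) become detections; a
   circular-Hough seeding pass catches round cells the tiling fragments, and
   tile-sized windows re-centred on tile edges are re-processed so a cell
   straddling an edge is found exactly once.
3. **Features** — per detection: centroid, area, extent (area / bounding-box
   area), perimeter (weighted boundary-step measure), major/minor axis and
   eccentricity of the ellipse with the region's normalized second central
   moments, max and mean intensity.
4. **Filtering** — declarative expert criteria (closed per-feature
   intervals, optional calcium-activity floor) split detections into kept
   and discarded; discarded cells can be erased to the background value on a
   copy of the frame.
5. **Tracking** — consecutive frames are linked by a gated minimum-cost
   assignment: cost = centroid distance + Σ wᵢ·normalized feature
   difference, admissible within a 20 px gate, solved optimally
   (maximum-cardinality, then minimum total cost). Unmatched detections are
   births; a track may coast through up to 2 missed frames with a
   proportionally enlarged gate before it dies.
6. **Summary** — min / mean / max / sample SD per measure over all
   (cell, time point) records, with per-step displacement on tracked input.

## A worked example

```sh
python examples/02_enhance_and_segment.py
```

prints (seeded, so reproducible):

```
raw intensity range 0..28248, enhanced 0..65535 (1% saturated at each end)
37 detections for 30 true cells (despite an illumination ramp of 30% of cell contrast)
recall 30/30, centroid RMSE 0.23 px (sub-pixel localization from the thresholded pixel sets)
```

All 30 simulated cells are recovered with sub-pixel centroid accuracy even
under a strong illumination gradient — the per-tile thresholds compensate —
while the extra detections are background noise that the filtering stage
(example 03) removes. The other examples cover simulation (01), noise-cell
filtering (03), tracking and summary tables (04) and the full
config-driven pipeline with on-disk artifacts and a reproducibility
manifest (05).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

simulates a 20-frame scene of 25 motile, flashing cells (two entering, two
leaving the field of view), runs the full pipeline — enhance, segment,
filter, track, summarize — and prints the detection/track counts and the
summary-statistics table computed from the tracked cells, writing its JSON
report to `--out`.
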