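# Methods

## Scope

`difchor` couples two models of the same biology. A *population* model turns
plating counts from dif-cassette excision assays into per-generation
recombination frequencies. A *single-cell* model simulates and analyses the
choreography of a fluorescently tagged terminus-proximal locus relative to
septum formation. The synthetic-data generator sits underneath both: it is
first-class, tested code whose ground truth drives every recovery and
equivalence test in the suite.

## Excision-assay estimator

Non-recombined cells decay geometrically with divisions, so
`Rf/Ri = (1-f)^n` and `f = 1 - exp(ln(Rf/Ri)/n)` with
`n = ln(Nf/Ni)/ln 2`. Choices:

- `Ri` defaults to exactly 1; a measured `Ri < 1` is honoured.
- `Rf` outside the 10–90% window triggers a warning rather than an error:
  the estimate is returned but poorly conditioned.
- Replicates are aggregated by computing `f` per replicate and averaging
  (matching per-experiment means of multi-replicate assays); pooling the
  ratios first is available behind `pooled=True`.
- Confidence intervals are percentile bootstraps over replicates of the
  plug-in estimate, deterministic given the seed.
- Negative recA-dependencies (`1 - f(recA-)/f(recA+)` when the recA− rate
  exceeds the recA+ rate) are reported verbatim with a warning, never
  clamped.

The plating simulator tracks each founder as an independent line of descent
that excises at each exponential-phase division with probability
`f_indep (+ f_dep if recA+)`; the per-division first-success time is
geometric. This has the same marginal non-recombined fraction `(1-f)^n` as a
full branching tree while staying O(founders). Lag and stationary phases are
modelled as contributing no divisions at all, so all recombination falls in
the exponential phase. Colony counts are binomial samples of the population
fraction.

## Single-cell model

Cells are rods of fixed width (1 µm default) with hemispherical caps that
elongate exponentially and divide symmetrically at a per-cell generation
time `T ~ N(T0, (cv·T0)^2)` (cv 0.08 by default; the cell-to-cell spread of
event timings is not constrained by published population data and is a
modelling choice). Two latent events are drawn per cell as cycle fractions
from truncated normals on [0, 1]:

- `t_sep` — sister-focus separation (slow-growth presets ≈ 0.82 ± 0.05,
  fast ≈ 0.40 ± 0.05),
- `t_con` — optically detectable constriction onset (slow ≈ 0.78, fast
  ≈ 0.62).

A single focus starts at `birth_focus_position` (new-pole-proximal, 0.75,
in slow presets; mid-cell in fast), glides linearly to mid-cell by
`midcell_arrival`, and at `t_sep` the two sisters appear at the
`post_sep_targets`. `relocation_time` defaults to 0 — the sisters jump to
their targets at the separation event. At the 2–4 min frame intervals of
the imaging protocol, separation and departure from mid-cell are observed
as concurrent, and an instantaneous jump also guarantees that no rendered
frame ever shows two foci inside the optical resolution limit, which keeps
"number of foci" well defined for both the renderer and the ground-truth
oracle. Slow presets use targets (0.375, 0.625) so that partitioning a
mother's foci at division reproduces the new-pole-proximal birth position
of her daughters (2 × 0.375 = 0.75); fast presets use the (0.25, 0.75)
quarter positions. In overlapping-rounds mode (fast growth), founders may
be born with two foci and each post-separation focus may split again late
in the cycle (probability 0.6 after ≈ 85% of the cycle), yielding the 3–4
focus classes; this is phenomenological inheritance bookkeeping, not a
replication model.

Every random draw comes from a stream keyed by (master seed, lineage
identifier, purpose) through SHA-256 hashing, so population size, duration
or unrelated options never reshuffle an individual cell.

## Rendering

Cells are laid out horizontally in per-founder lanes; daughters replace the
mother side by side with a 6 px visible gap (real scission separates cells
optically; the gap also lets the conservative segmenter distinguish true
scission from deep constriction). Fluorescence is background plus isotropic
Gaussian spots (σ = PSF σ) at the jittered true focus positions plus
per-pixel Gaussian noise. Bright field is a defocus stack whose cell-body
contrast is proportional to signed defocus with defocus-dependent blur, so
the per-pixel standard deviation across the stack reconstructs the cell
shape. From `t_con` onward a transverse Gaussian dark line (σ 1.5 px) is
drawn at mid-cell, its depth ramping from 0.45 to 0.65 of body contrast
over 10 min — deep enough to detect at onset, shallow enough that a
closed (radius-2) morphological pass keeps the constricting cell one
segment.

What the generator deliberately does not emulate: diffraction beyond a
Gaussian PSF, phase-contrast optics, cell bending or width variation,
crowded colonies with touching neighbours, photobleaching, or uneven
illumination. Tests passing on these synthetics therefore demonstrate the
internal consistency of the pipeline (segmentation → tracking → statistics
recovers exactly what was simulated), not robustness to every artefact of
real microscopy.

## Imaging pipeline

- **Shape reconstruction**: per-pixel std (default) or range projection
  across the bright-field stack.
- **Segmentation**: Otsu threshold, radius-2 closing (bridges the septal
  dark line), connected components, minimum area 0.8 µm². Blank images
  yield empty results, not errors.
- **Pole localisation**: the transverse-sum longitudinal profile of a
  capsule is proportional to its chord length, so poles come from a
  least-squares fit of a Gaussian-blurred chord model (offset, amplitude,
  two poles, cap radius, blur). Plain half-maximum crossings of
  transverse-averaged profiles sit systematically ~0.13·r inside rounded
  poles; the explicit cap model removes that bias (residual ≈ 0.1 px) and
  is robust to intensity bleeding across the inter-cell gap. Half-maximum
  crossing remains as a fallback.
- **Tracking**: frame-to-frame assignment by maximal mask overlap, ties
  broken by centroid distance. A one-to-two event is a provisional
  division, accepted once the two daughters stay distinct with a gap
  ≥ 2 px for 2 consecutive frames; unconfirmable splits keep the larger
  fragment on the mother's track and flag the other. After a confirmed
  division each daughter's new pole is the end adjacent to its sibling;
  axis orientation is kept consistent frame to frame so polarity never
  flips within a life. Only cells observed from birth to their own
  confirmed division ("complete cycles") enter the choreography
  statistics.
- **Septation detection**: per frame, a quadratic baseline is fit to the
  central 60% of the (~2 px-binned) shape profile; the deepest local
  minimum in the central [0.35, 0.65] window is a constriction candidate
  when it undercuts the re-fit baseline by ≥ 3 × the robust residual MAD
  *and* by ≥ 20% of the profile's dynamic range. The call requires the dip
  to persist on the next frame at a consistent position (±0.10 of cell
  length): a real septum is stationary, noise dips land at random
  positions. The depth floor and positional persistence are this package's
  additions to the plain k·MAD rule; without them, deepest-of-many-bins
  noise excursions produce premature calls. Detection cannot precede the
  physical onset; on synthetic movies with default noise it lands on the
  first post-onset frame in ≳ 95% of cells.
- **Focus detection**: Laplacian-of-Gaussian response at the PSF scale,
  local maxima within the cell mask, minimum separation 2σ (brighter peak
  wins), at most four reported. Peaks must exceed the in-cell
  median + max(5 × 1.4826 MAD, 10% of the in-cell 99th-percentile
  excess) — the absolute floor rejects PSF tails bleeding in from
  neighbouring cells, which otherwise qualify in noise-free images where
  the MAD vanishes. Sub-pixel positions are intensity-weighted centroids,
  projected between the fitted poles and oriented old pole → new pole
  (or mirrored at random, seeded, in snapshot mode).

## Kymographs, consensus, aligned statistics

Per-frame profiles are min–max normalised (constant profiles map to zeros,
flagged), resampled by linear interpolation onto a 101 × 101 (cycle time ×
relative length) grid, rows re-normalised; resampling at the native grid is
the identity to interpolation tolerance. Consensus images are plain
element-wise means, so each complete cycle contributes equally. The
consensus split-time estimator reads the mean intensity of the central
±4% column band down the rows: in row-normalised kymographs it tracks the
fraction of cells whose sisters have not yet separated, and its half-way
crossing after the plateau estimates the median `t_sep`.

Aligned statistics re-index each cell's frames so the septation call is
offset 0 and report, per offset: focus-count frequencies (0/1/2/3+, summing
to 1), cells at risk (single-focus), persistent 1→2 transitions, and median
focus positions. A 1→2 transition counts only if the 2-focus state holds
for two consecutive frames (guards against blinking); focus-count decreases
are kept but never scored as reverse duplications. The duplication rate at
an offset is transitions / at-risk / frame-interval × 100 (%/min). The
mid-cell criterion is strictly `d < 0.05` cell lengths; a focus at exactly
0.05 is excluded. All statistics operate on tidy per-cell-per-frame tables,
so the identical code summarises either pipeline measurements or simulator
ground truth — the oracle-equivalence tests compare the two routes on the
same statistic.

## Problem sizes and numerical tolerances

The test suite exercises: estimator round trips to 1e-12 over
f ∈ [0, 0.9], n ∈ [1, 30]; plating round trips with 10⁴ lineages, 20
divisions, 200 colonies per plate, 100 single-plate replicates for the mean
and 100 × 20-plate experiments for bootstrap coverage (20 plates per
experiment because percentile bootstraps over very small replicate sets
undercover); oracle equivalence and parameter recovery on 200 complete cell
cycles from single-founder movies (7 bright-field planes for noise-free
runs, 16 with default noise) plus 200 single-cell snapshots. Positions
agree with ground truth to ≤ 0.01 cell lengths at the statistic level
(medians); individual foci are recovered to ≈ 0.004 median, ≈ 0.013
worst-case, dominated by pole-fit residuals on the shortest cells.

## Known limitations

- The segmentation is built for sparse agarose-pad fields; it does not
  split touching cells within a frame (divisions are resolved by the
  tracker, not the segmenter).
- Pole-fit accuracy assumes capsule geometry; strongly bent or tapered
  cells would bias relative positions.
- The overlapping-rounds focus model reproduces focus counts and coarse
  positions, not replisome dynamics; filament (no-scission) mode renders
  but has no dedicated analysis.
- Septation detection reports the first *optically detectable* dip; any
  physical latency between constriction initiation and optical visibility
  is outside the model, so detection latencies quantified here are lower
  bounds for real data.
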