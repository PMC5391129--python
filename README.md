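# difchor

Simulation and analysis tools for two complementary readouts of how bacteria
coordinate the final steps of chromosome segregation with cell division:

1. **dif-cassette excision assays.** A reporter cassette flanked by two *dif*
   sites is excised by the XerCD recombinases under FtsK control, turning
   blue colonies white on X-Gal plates. The per-generation excision frequency
   and its *recA*-dependency quantify how often the chromosomal terminus is
   processed by FtsK at the septum.
2. **Single-cell choreography of the terminus locus.** Time-lapse movies
   (one fluorescence channel for a tagged *ter*-proximal locus plus a
   bright-field defocus stack) and snapshot image sets are reduced to
   per-cell, cell-cycle-normalised kymographs, population consensus images,
   septation-onset calls, and focus-count statistics aligned on the first
   detected constriction.

A fully seeded synthetic-data generator produces cell lineages, rendered
movies, snapshot populations and plating counts with known ground truth, so
every stage of the analysis is exercisable and testable without external
data.

## The core quantities

**Excision frequency.** With `Ri` and `Rf` the initial and final fractions of
non-recombined (blue) cells and `n = ln(Nf/Ni)/ln 2` the number of divisions
deduced from the cell counts, the per-generation excision probability is

```
f = 1 - exp(ln(Rf / Ri) / n)        (Ri = 1 for fresh cultures)
```

`Rf` is best monitored in the 10–90% window; values outside it carry a
warning. The *recA*-dependency of excision — the fraction of the rate
attributable to homologous-recombination-generated chromosome dimers — is
`1 - f(recA-) / f(recA+)`.

**Choreography.** Each frame of a complete cell cycle (birth to division,
polarity fixed by the observed birth division) is reduced to a longitudinal
intensity profile, min–max normalised, oriented old pole → new pole and
resampled onto a normalised (cycle time × cell length) grid. Averaging these
per-cell kymographs gives consensus images in which every cell contributes
equally. Septation onset is the first frame in which a persistent transverse
dark line at mid-cell undercuts a smooth baseline of the bright-field shape
profile. Focus statistics (1/2/3+ counts, mid-cell proximity at the strict
`d < 0.05` cell-length criterion, duplication rates in %/min) are computed
per cell and aligned on the septation call.

## Worked example

Estimate excision rates and *recA*-dependency from a plating-count table
(`counts.csv` with columns `replicate, condition, Ni, Nf, colonies_total_i,
colonies_white_i, colonies_total_f, colonies_white_f`):

```sh
difchor assay --counts counts.csv --out assay_out
```

For a table with three replicates at `Rf = 36.4%` over `n = 19.3` divisions
(recA+) and `Rf = 79.8%` over `n = 19.9` (recA−) this prints:

```
condition        f    n   ci_low  ci_high  n_replicates warnings
 LB recA+ 0.051015 19.3 0.051015 0.051015             3
 LB recA- 0.011275 19.9 0.011275 0.011275             3
recA-dependency (LB recA+ vs LB recA-): 0.779
```

i.e. an excision rate of ~5.1% per generation that drops to ~1.1% without
RecA — roughly 78% of excision events depend on homologous recombination
under this fast-growth condition.

Simulate, render and analyse a movie in one go:

```sh
difchor endtoend --preset Ec-slow --seed 1 --founders 3 --out run1
```

which writes the rendered movie (multi-page TIFF + ground-truth CSV), the
per-cell and per-focus tables, the septation-aligned series and the
fluorescence/shape consensus images (16-bit TIFF and jet-colormap PNG).
Presets `Ec-slow`, `Ec-fast`, `Vc-slow`, `Vc-fast`, `dMatP` and `ftsK-ATP-`
encode the growth-condition and mutant timing regimes; in `Ec-slow` sister
foci separate at ~80% of the cycle together with the visible onset of
constriction, while in `Ec-fast` they separate at ~40%, well before it.

From Python, the same pipeline is three calls:

```python
import difchor as dc

cfg = dc.preset("Ec-slow", seed=1)
_, truth = dc.simulate_population(cfg, duration=2.2 * cfg.generation_time, seed=1)
movie = dc.render_movie(truth)
analysis = dc.analyze_movie(movie, dc.AnalyzeParams(psf_sigma_px=cfg.psf_sigma_px()))
analysis.aligned.table          # focus-count frequencies vs time from septation
analysis.consensus["fluor"]     # 101 x 101 consensus kymograph
```

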