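"""Focus detection and snapshot / septation-aligned statistics."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

import difchor as dc
from difchor.config import SimulationConfig
from difchor import foci_stats as fs
from difchor.imaging import reconstruct_shape_image, segment_cells, subpixel_poles


def _render_single_cell(birth_focus, t_frac=0.0, extra_focus=None, seed=0):
    """One zero-noise cell with a focus at a known relative position."""
    cfg = SimulationConfig(generation_time=40.0, generation_time_cv=0.0,
                           birth_length_cv=0.0, birth_length_mean=3.5,
                           t_sep_mean=0.99, t_sep_sd=0.0, t_con_mean=0.99,
                           t_con_sd=0.0, focus_jitter_sd=0.0, noise_sd=0.0,
                           n_stack_planes=5, frame_interval=2.0,
                           birth_focus_position=birth_focus, midcell_arrival=0.99)
    _, truth = dc.simulate_population(cfg, 40.0, seed=seed)
    t = t_frac * cfg.generation_time
    movie = dc.render_movie(truth, times=np.array([t]))
    shape = reconstruct_shape_image(movie.brightfield[0], cfg.pixel_size)
    (region,) = segment_cells(shape)
    poles = subpixel_poles(shape.data, region)
    fluor = movie.fluorescence[0].copy()
    if extra_focus is not None:
        lay = movie.layout.iloc[0]
        x = lay.x0 + extra_focus * lay.length_px
        from difchor.render import _add_spot
        _add_spot(fluor, x, lay.y, cfg.spot_amplitude, cfg.psf_sigma_px())
    return cfg, movie, fluor, region, poles


class TestDetectFoci:
    def test_single_spot_position_recovered(self):
        cfg, movie, fluor, region, poles = _render_single_cell(0.30)
        found = fs.detect_foci(fluor, region, cfg.psf_sigma_px(), poles=poles)
        assert len(found) == 1
        assert found[0].x == pytest.approx(0.30, abs=0.01)

    def test_blank_cell_has_no_foci(self):
        cfg, movie, fluor, region, poles = _render_single_cell(0.30)
        blank = np.full_like(fluor, cfg.background)
        assert fs.detect_foci(blank, region, cfg.psf_sigma_px(), poles=poles) == []

    def test_two_well_separated_spots(self):
        # second spot 0.4 cell lengths away: >> 5 PSF sigma
        cfg, movie, fluor, region, poles = _render_single_cell(0.30, extra_focus=0.70)
        found = fs.detect_foci(fluor, region, cfg.psf_sigma_px(), poles=poles)
        assert len(found) == 2
        xs = sorted(f.x for f in found)
        assert xs[0] == pytest.approx(0.30, abs=0.01)
        assert xs[1] == pytest.approx(0.70, abs=0.01)

    def test_at_most_four_reported(self):
        cfg, movie, fluor, region, poles = _render_single_cell(0.10)
        from difchor.render import _add_spot
        lay = movie.layout.iloc[0]
        for u in (0.3, 0.5, 0.7, 0.9):
            _add_spot(fluor, lay.x0 + u * lay.length_px, lay.y,
                      cfg.spot_amplitude, cfg.psf_sigma_px())
        found = fs.detect_foci(fluor, region, cfg.psf_sigma_px(), poles=poles)
        assert len(found) == fs.MAX_FOCI == 4


class TestMidcellFraction:
    def test_two_of_three_within_threshold(self):
        assert fs.midcell_fraction([0.01, 0.04, 0.20]) == pytest.approx(2 / 3)

    def test_polar_foci_score_zero(self):
        assert fs.midcell_fraction([0.5, 0.5, 0.5]) == 0.0

    def test_boundary_is_strictly_excluded(self):
        assert fs.midcell_fraction([0.05]) == 0.0
        assert fs.midcell_fraction([np.nextafter(0.05, 0.0)]) == 1.0

    def test_accepts_focus_observations(self):
        foci = [fs.FocusObservation(cell=0, frame=0, x=0.52, intensity=1.0),
                fs.FocusObservation(cell=0, frame=0, x=0.90, intensity=1.0)]
        assert fs.midcell_fraction(foci) == 0.5

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            fs.midcell_fraction([])


class TestSnapshotStats:
    def test_uniform_population_single_class(self):
        cells = pd.DataFrame(dict(cell=range(10), length=3.0,
                                  constricting=False, n_foci=1))
        foci = pd.DataFrame(dict(cell=range(10), x=[0.5] * 10))
        summ = fs.snapshot_stats(cells, foci)
        assert summ.count(False, "1") == 10
        assert summ.count(True, "1") == 0
        assert summ.count(False, "2") == 0
        assert summ.n_cells == 10

    def test_class_counts_sum_to_population(self):
        rng = np.random.default_rng(0)
        n = 40
        cells = pd.DataFrame(dict(cell=range(n), length=rng.uniform(2, 6, n),
                                  constricting=rng.random(n) < 0.3,
                                  n_foci=rng.integers(1, 5, n)))
        foci = pd.DataFrame([dict(cell=c, x=rng.random())
                             for c in cells.cell for _ in range(int(cells.n_foci[c]))])
        summ = fs.snapshot_stats(cells, foci)
        assert summ.class_counts["cells"].sum() == n

    def test_empty_population(self):
        summ = fs.snapshot_stats(pd.DataFrame(columns=["cell", "length",
                                                       "constricting", "n_foci"]),
                                 pd.DataFrame(columns=["cell", "x"]))
        assert summ.n_cells == 0
        assert summ.class_counts.empty


def _aligned_tables(per_cell):
    """Build cell_frames/foci tables from {cell: (sept_frame, [n_foci...])}."""
    cf, foci = [], []
    for cell, (sept, counts, xs) in per_cell.items():
        for i, n in enumerate(counts):
            cf.append(dict(cell=cell, frame=i, n_foci=n, sept_frame=sept))
            for x in xs.get(i, [0.5] * n):
                foci.append(dict(cell=cell, frame=i, x=x))
    return pd.DataFrame(cf), pd.DataFrame(foci)


class TestAlignedSeries:
    def test_septation_frame_maps_to_offset_zero(self):
        cf, foci = _aligned_tables({"a": (7, [1] * 10, {})})
        series = fs.align_to_septation(cf, foci, frame_interval=2.0)
        t = series.table
        assert t.loc[t.offset_min == 0.0, "n_cells"].iloc[0] == 1
        assert t.offset_min.min() == -14.0

    def test_all_two_focus_cells_have_zero_single_frequency(self):
        cf, foci = _aligned_tables({c: (3, [2] * 6, {}) for c in "abc"})
        series = fs.align_to_septation(cf, foci, frame_interval=2.0)
        row = series.table[series.table.offset_min == 0.0].iloc[0]
        assert row.freq1 == 0.0 and row.freq2 == 1.0

    def test_frequencies_sum_to_one_at_every_offset(self):
        rng = np.random.default_rng(1)
        per_cell = {f"c{i}": (int(rng.integers(2, 6)),
                              list(rng.integers(1, 4, size=8)), {})
                    for i in range(12)}
        cf, foci = _aligned_tables(per_cell)
        series = fs.align_to_septation(cf, foci, frame_interval=2.0)
        sums = series.table[["freq0", "freq1", "freq2", "freq3+"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)

    def test_no_septation_calls_is_an_error(self):
        cf = pd.DataFrame(dict(cell=["a"], frame=[0], n_foci=[1],
                               sept_frame=[np.nan]))
        with pytest.raises(ValueError):
            fs.align_to_septation(cf, pd.DataFrame(columns=["cell", "frame", "x"]),
                                  frame_interval=2.0)


class TestDuplicationRate:
    def test_ten_of_fifty_over_two_minutes(self):
        per_cell = {}
        for i in range(50):
            counts = [1, 2, 2] if i < 10 else [1, 1, 1]
            per_cell[f"c{i}"] = (0, counts, {})
        cf, foci = _aligned_tables(per_cell)
        series = fs.align_to_septation(cf, foci, frame_interval=2.0)
        assert fs.duplication_rate(series, 0.0) == pytest.approx(10.0)

    def test_zero_transitions(self):
        cf, foci = _aligned_tables({f"c{i}": (0, [1] * 4, {}) for i in range(5)})
        series = fs.align_to_septation(cf, foci, frame_interval=2.0)
        assert fs.duplication_rate(series, 0.0) == 0.0

    def test_unpersistent_blink_not_counted(self):
        cf, foci = _aligned_tables({"a": (0, [1, 2, 1, 1], {})})
        series = fs.align_to_septation(cf, foci, frame_interval=2.0)
        assert fs.duplication_rate(series, 0.0) == 0.0

    def test_no_at_risk_cells_is_an_error(self):
        cf, foci = _aligned_tables({"a": (0, [2, 2, 2], {})})
        series = fs.align_to_septation(cf, foci, frame_interval=2.0)
        with pytest.raises(ValueError):
            fs.duplication_rate(series, 0.0)

    def test_constant_hazard_recovered(self):
        """Geometric separation times: rate at offset 0 within 3 SE of 100 h."""
        h, dt, n = 0.02, 2.0, 500          # per-minute hazard, frame interval
        rng = np.random.default_rng(7)
        per_cell = {}
        for i in range(n):
            # first duplication frame ~ geometric with per-frame prob h*dt
            k = rng.geometric(h * dt)
            counts = [1] * min(k, 10) + [2] * max(0, 12 - min(k, 10))
            per_cell[f"c{i}"] = (0, counts[:12], {})
        cf, foci = _aligned_tables(per_cell)
        series = fs.align_to_septation(cf, foci, frame_interval=dt)
        rate = fs.duplication_rate(series, 0.0)
        at_risk = series.table.loc[series.table.offset_min == 0.0, "at_risk"].iloc[0]
        p = h * dt
        se = 100.0 * math.sqrt(p * (1 - p) / at_risk) / dt
        assert rate == pytest.approx(100.0 * h, abs=3 * se)


def test_randomized_orientation_is_symmetric():
    """Random flips make left/right counts binomial(n, 1/2)."""
    n = 400
    foci = pd.DataFrame(dict(cell=np.arange(n), x=np.full(n, 0.25)))
    flipped = fs.randomize_orientation(foci, seed=11)
    left = int((flipped.x < 0.5).sum())
    assert binomtest(left, n, 0.5).pvalue >= 0.01
    # flip only mirrors, never moves positions
    assert set(np.round(flipped.x, 6)) <= {0.25, 0.75}
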