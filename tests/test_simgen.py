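"""Simulator: choreography model, reproducibility, plating statistics."""

import dataclasses
import math

import numpy as np
import pytest

import difchor as dc
from difchor.config import PlatingSimConfig, SimulationConfig
from difchor import xer_assay as xa


def _exact_cfg(**kw):
    """Slow-growth configuration with all cell-to-cell variability removed."""
    base = dict(generation_time=40.0, generation_time_cv=0.0,
                birth_length_cv=0.0, t_sep_mean=0.8, t_sep_sd=0.0,
                t_con_mean=0.75, t_con_sd=0.0, focus_jitter_sd=0.0,
                birth_focus_position=0.5, frame_interval=2.0, noise_sd=0.0,
                n_stack_planes=4)
    base.update(kw)
    return SimulationConfig(**base)


class TestFocusChoreography:
    def test_single_focus_at_midcell_before_separation(self):
        cfg = _exact_cfg()
        _, truth = dc.simulate_population(cfg, 40.0, seed=0)
        cell = truth.cells["0"]
        pos = truth.foci(cell, 0.5 * cfg.generation_time)
        assert pos == [pytest.approx(0.5)]

    def test_two_foci_after_separation(self):
        cfg = _exact_cfg()
        _, truth = dc.simulate_population(cfg, 40.0, seed=0)
        cell = truth.cells["0"]
        pos = truth.foci(cell, 0.9 * cfg.generation_time)
        assert len(pos) == 2
        lo, hi = cfg.post_sep_targets
        assert pos == [pytest.approx(lo), pytest.approx(hi)]

    def test_birth_focus_glides_to_midcell(self):
        cfg = _exact_cfg(birth_focus_position=0.75, midcell_arrival=0.5)
        _, truth = dc.simulate_population(cfg, 40.0, seed=0)
        cell = truth.cells["0"]
        assert truth.foci(cell, 0.0) == [pytest.approx(0.75)]
        assert truth.foci(cell, 0.25 * cfg.generation_time) == [pytest.approx(0.625)]
        assert truth.foci(cell, 0.5 * cfg.generation_time) == [pytest.approx(0.5)]

    def test_population_doubles_every_generation(self):
        cfg = _exact_cfg()
        _, truth = dc.simulate_population(cfg, 120.0, seed=0)
        assert len(truth.cells_alive(120.0)) == 8      # 2^3

    def test_filament_mode_never_divides(self):
        cfg = _exact_cfg(scission_enabled=False)
        _, truth = dc.simulate_population(cfg, 120.0, seed=0)
        assert len(truth.cells) == 1
        assert len(truth.cells_alive(120.0)) == 1

    def test_duration_must_cover_a_generation(self):
        with pytest.raises(ValueError):
            dc.simulate_population(_exact_cfg(), 10.0, seed=0)

    def test_daughters_partition_mother_foci(self):
        """Foci conservation at scission: daughters inherit the mother's foci."""
        cfg = _exact_cfg()
        _, truth = dc.simulate_population(cfg, 90.0, seed=0)
        mother = truth.cells["0"]
        m_foci = truth._foci_positions(mother, 1.0)
        d_born = [truth.cells[d].born_foci for d in mother.daughters]
        assert sum(len(b) for b in d_born) == len(m_foci)
        # old-side daughter carries the focus at 2x, new-side at 2(1-x)
        lo, hi = sorted(m_foci)
        assert d_born[0] == (pytest.approx(2 * lo),)
        assert d_born[1] == (pytest.approx(2 * (1 - hi)),)

    def test_polarity_alternates_between_daughters(self):
        cfg = _exact_cfg()
        _, truth = dc.simulate_population(cfg, 90.0, seed=0)
        mother = truth.cells["0"]
        d_old, d_new = (truth.cells[d] for d in mother.daughters)
        assert d_old.orient == mother.orient
        assert d_new.orient == -mother.orient


class TestReproducibility:
    def test_identical_seed_identical_truth(self):
        cfg = dc.preset("Ec-slow", n_stack_planes=4)
        _, t1 = dc.simulate_population(cfg, 1.5 * cfg.generation_time, seed=11)
        _, t2 = dc.simulate_population(cfg, 1.5 * cfg.generation_time, seed=11)
        a, b = t1.cell_frame_table(False), t2.cell_frame_table(False)
        assert a.equals(b)
        fa, fb = t1.foci_table(False), t2.foci_table(False)
        assert fa.equals(fb)

    def test_founder_streams_independent_of_population_size(self):
        """Adding founders never reshuffles an existing cell's draws."""
        cfg = dc.preset("Ec-slow", n_stack_planes=4)
        _, t1 = dc.simulate_population(cfg, 1.2 * cfg.generation_time, seed=5,
                                       n_founders=1)
        _, t3 = dc.simulate_population(cfg, 1.2 * cfg.generation_time, seed=5,
                                       n_founders=3)
        c1, c3 = t1.cells["0"], t3.cells["0"]
        assert (c1.gen_time, c1.t_sep, c1.t_con) == (c3.gen_time, c3.t_sep, c3.t_con)

    def test_plating_deterministic(self):
        pcfg = PlatingSimConfig(seed=4)
        assert dc.simulate_plating(pcfg) == dc.simulate_plating(pcfg)


class TestSnapshotSampling:
    def test_flip_mirrors_positions(self):
        cfg = _exact_cfg(birth_focus_position=0.2, midcell_arrival=0.9)
        _, truth = dc.simulate_population(cfg, 40.0, seed=0)
        cell = truth.cells["0"]
        true_pos = truth.foci(cell, 0.0, frame=0)
        for seed in range(8):
            obs = dc.snapshot_sample(truth, 0.0, seed=seed)[0]
            expected = sorted(1 - x for x in true_pos) if obs.flipped \
                else sorted(true_pos)
            assert list(obs.foci) == pytest.approx(expected)

    def test_midcycle_slow_population_all_single_focus(self):
        cfg = _exact_cfg()
        _, truth = dc.simulate_population(cfg, 60.0, seed=1)
        obs = dc.snapshot_sample(truth, 60.0, seed=0)    # all cells at age 0.5
        assert obs and all(o.n_foci == 1 for o in obs)

    def test_length_span_covers_birth_to_division(self):
        cfg = dc.preset("Ec-slow", n_stack_planes=4)
        lengths = []
        for k in range(24):
            _, truth = dc.simulate_population(
                cfg, cfg.generation_time + 1, seed=60 + k,
                founder_age=(k / 24) * 0.95)
            lengths += [o.length for o in dc.snapshot_sample(truth, 2.0, seed=0)]
        assert max(lengths) / min(lengths) >= 1.8

    def test_time_outside_window_rejected(self):
        cfg = _exact_cfg()
        _, truth = dc.simulate_population(cfg, 40.0, seed=0)
        with pytest.raises(ValueError):
            dc.snapshot_sample(truth, 1e4, seed=0)


class TestPlatingAssay:
    def test_no_excision_no_white_colonies(self):
        pc = dc.simulate_plating(PlatingSimConfig(f_indep=0.0, f_dep=0.0, seed=0))
        assert pc.Rf == 1.0 and pc.colonies_white_f == 0

    def test_certain_excision_recombines_everything(self):
        pc = dc.simulate_plating(PlatingSimConfig(
            f_indep=1.0, f_dep=0.0, n_generations_exp=1, seed=0))
        assert pc.Rf == 0.0

    def test_reca_minus_drops_dependent_component(self):
        plus = PlatingSimConfig(f_indep=0.01, f_dep=0.04, recA_plus=True, seed=1)
        minus = dataclasses.replace(plus, recA_plus=False)
        assert plus.f_total == pytest.approx(0.05)
        assert minus.f_total == pytest.approx(0.01)

    def test_growth_counts_follow_doubling(self):
        pcfg = PlatingSimConfig(n_generations_exp=12, initial_cells=500, seed=0)
        pc = dc.simulate_plating(pcfg)
        assert pc.Nf / pc.Ni == pytest.approx(2.0 ** 12)
        assert xa.count_divisions(pc.Ni, pc.Nf) == pytest.approx(12.0)

    def test_zero_colonies_rejected(self):
        with pytest.raises(ValueError):
            dc.simulate_plating(PlatingSimConfig(colonies_sampled=0))

    def test_nonrecombined_fraction_matches_closed_form(self):
        """Mean final non-recombined fraction -> (1-f)^n within 3 SE."""
        f, n = 0.05, 20
        pcfg = PlatingSimConfig(f_indep=f, f_dep=0.0, n_generations_exp=n,
                                initial_cells=10_000, colonies_sampled=5000)
        rfs = np.array([dc.simulate_plating(pcfg, seed=s).Rf for s in range(30)])
        expected = (1 - f) ** n
        se = rfs.std(ddof=1) / math.sqrt(len(rfs))
        assert abs(rfs.mean() - expected) < 3 * se

    def test_lag_and_stationary_add_no_divisions(self):
        a = PlatingSimConfig(seed=2)
        b = dataclasses.replace(a, lag_divisions=3, stationary_divisions=2)
        assert dc.simulate_plating(a) == dc.simulate_plating(b)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            PlatingSimConfig(f_indep=0.9, f_dep=0.2)
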