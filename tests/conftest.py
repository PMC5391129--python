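"""Shared fixtures: small simulated/rendered/analysed movies.

Everything is generated at run time from seeds; no stored image data.
"""

from __future__ import annotations

import numpy as np
import pytest

import difchor as dc


@pytest.fixture(scope="session")
def slow_zero_cfg():
    """Zero-noise slow-growth configuration with a thin bright-field stack."""
    return dc.zero_noise(dc.preset("Ec-slow", seed=0, n_stack_planes=7))


@pytest.fixture(scope="session")
def zero_movie_batch(slow_zero_cfg):
    """Four single-founder zero-noise movies, analysed, with truth mapping."""
    out = []
    for seed in range(4):
        cfg = slow_zero_cfg
        roots, truth = dc.simulate_population(cfg, 2.2 * cfg.generation_time,
                                              seed=seed)
        movie = dc.render_movie(truth)
        ana = dc.analyze_movie(movie, dc.AnalyzeParams(psf_sigma_px=cfg.psf_sigma_px()))
        mapping = dc.match_tracks(ana, movie)
        out.append((truth, movie, ana, mapping))
    return out


@pytest.fixture(scope="session")
def single_cell_movie(slow_zero_cfg):
    """One zero-noise founder observed over one generation (no division)."""
    import dataclasses
    cfg = dataclasses.replace(slow_zero_cfg, scission_enabled=False,
                              generation_time_cv=0.0)
    roots, truth = dc.simulate_population(cfg, cfg.generation_time, seed=3)
    movie = dc.render_movie(truth)
    return truth, movie
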