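"""Synthetic single-cell lineages, snapshot populations and plating counts.

The generator produces exponentially elongating rod cells carrying a single
tracked chromosomal locus.  Each cell draws its generation time, its
sister-separation time ``t_sep`` and its constriction-onset time ``t_con``
(both cycle fractions, truncated normal).  Before separation the cell shows a
single focus that migrates from its birth position to mid-cell; at separation
the two sister foci appear at the configured post-separation targets.  In
overlapping-rounds mode (fast growth) cells may be born with two foci and
post-separation foci may split again late in the cycle, yielding 3-4 foci.

Randomness is fully reproducible: every cell derives its own stream from the
master seed by stable hashing of its lineage identifier, so enlarging the
population or changing the duration never reshuffles an individual cell.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import PlatingSimConfig, SimulationConfig
from .xer_assay import PlatingCounts

__all__ = [
    "SimCell",
    "GroundTruth",
    "CellObservation",
    "simulate_population",
    "snapshot_sample",
    "simulate_plating",
    "simulate_plating_replicates",
]


def _stream(seed: int, *keys) -> np.random.Generator:
    """Deterministic child RNG keyed by arbitrary hashable labels."""
    digest = hashlib.sha256("/".join(map(str, keys)).encode()).digest()
    spawn = tuple(int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=spawn))


def _truncnorm01(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return float(np.clip(mean, 0.0, 1.0))
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


@dataclass
class SimCell:
    """One simulated cell: latent cycle parameters and lineage links.

    Relative ("internal") coordinates run 0 -> 1 from the old pole to the new
    pole.  ``orient`` records how the internal axis maps onto the rendering
    lane: +1 means internal coordinates increase with lane x.
    """

    id: str
    parent: str | None
    birth_time: float
    gen_time: float
    birth_length: float
    t_sep: float                      # cycle fraction
    t_con: float                      # cycle fraction
    orient: int = 1
    born_foci: tuple[float, ...] = (0.5,)
    late_splits: tuple[float, ...] = ()   # split time (cycle fraction) per target slot; nan = none
    daughters: tuple[str, str] | None = None   # (old-pole side, new-pole side)
    division_time: float = math.inf

    @property
    def t_sep_abs(self) -> float:
        return self.birth_time + self.t_sep * self.gen_time

    @property
    def t_con_abs(self) -> float:
        return self.birth_time + self.t_con * self.gen_time


class GroundTruth:
    """Latent truth for a simulated population, with oracle table builders."""

    def __init__(self, config: SimulationConfig, duration: float, seed: int,
                 cells: dict[str, SimCell], roots: list[str]):
        self.config = config
        self.duration = duration
        self.seed = seed
        self.cells = cells
        self.roots = roots

    # -- time grid ---------------------------------------------------------
    def frame_times(self) -> np.ndarray:
        dt = self.config.frame_interval
        n = int(math.floor(self.duration / dt + 1e-9)) + 1
        return np.arange(n) * dt

    def alive(self, cell: SimCell, t: float) -> bool:
        return cell.birth_time <= t < cell.division_time

    def cells_alive(self, t: float) -> list[SimCell]:
        return [c for c in self.cells.values() if self.alive(c, t)]

    def length(self, cell: SimCell, t: float) -> float:
        cfg = self.config
        g = cfg.growth_rate if cfg.growth_rate is not None else math.log(2.0) / cell.gen_time
        return cell.birth_length * math.exp(g * (t - cell.birth_time))

    # -- focus choreography ------------------------------------------------
    def _foci_positions(self, cell: SimCell, phi: float) -> list[float]:
        """Deterministic relative focus positions at cycle fraction *phi*."""
        cfg = self.config
        lo, hi = cfg.post_sep_targets
        reloc = cfg.relocation_time / cell.gen_time

        def _late(slot: int, base: float) -> list[float]:
            ts = cell.late_splits[slot] if slot < len(cell.late_splits) else math.nan
            if cfg.overlap_rounds and not math.isnan(ts) and phi >= ts:
                return [base - cfg.late_split_offset, base + cfg.late_split_offset]
            return [base]

        if len(cell.born_foci) == 1:
            b = cell.born_foci[0]
            if phi < cell.t_sep:
                if phi < cfg.midcell_arrival and cfg.midcell_arrival > 0:
                    return [b + (0.5 - b) * phi / cfg.midcell_arrival]
                return [0.5]
            # separated: jump (or glide) to targets, then possible late splits
            if reloc > 0:
                u = min(1.0, (phi - cell.t_sep) / reloc)
            else:
                u = 1.0
            p_lo = 0.5 + (lo - 0.5) * u
            p_hi = 0.5 + (hi - 0.5) * u
            return _late(0, p_lo) + _late(1, p_hi)
        # born with two foci (overlapping rounds): glide to the targets by t_sep
        b1, b2 = sorted(cell.born_foci)
        u = 1.0 if cell.t_sep <= 0 else min(1.0, phi / cell.t_sep)
        p_lo = b1 + (lo - b1) * u
        p_hi = b2 + (hi - b2) * u
        return _late(0, p_lo) + _late(1, p_hi)

    def foci(self, cell: SimCell, t: float, frame: int | None = None) -> list[float]:
        """Relative focus positions at absolute time *t* (jittered per frame)."""
        phi = (t - cell.birth_time) / cell.gen_time
        pos = self._foci_positions(cell, min(phi, 2.0))
        sd = self.config.focus_jitter_sd
        if frame is not None and sd > 0:
            rng = _stream(self.seed, "jitter", cell.id, frame)
            pos = list(np.asarray(pos) + rng.normal(0.0, sd, size=len(pos)))
        return [float(np.clip(p, 0.02, 0.98)) for p in pos]

    # -- observability conventions (shared with the imaging pipeline) ------
    def frames_of(self, cell: SimCell) -> np.ndarray:
        times = self.frame_times()
        return np.nonzero((times >= cell.birth_time - 1e-9)
                          & (times < cell.division_time - 1e-9))[0]

    def division_confirmed(self, cell: SimCell) -> bool:
        """Division observable: two daughter frames fit inside the movie."""
        if not math.isfinite(cell.division_time) or cell.daughters is None:
            return False
        times = self.frame_times()
        after = times[times >= cell.division_time - 1e-9]
        return len(after) >= 2

    def complete(self, cell: SimCell) -> bool:
        """Observed from birth to own division (the only cells analysed)."""
        return (cell.parent is not None
                and len(self.frames_of(cell)) >= 3
                and self.division_confirmed(cell))

    def septation_frame(self, cell: SimCell) -> int | None:
        """First frame with a detectable septum, requiring one-frame persistence."""
        times = self.frame_times()
        frames = self.frames_of(cell)
        for i in frames:
            if times[i] >= cell.t_con_abs - 1e-9:
                if i + 1 in frames:   # dip must persist on the next frame
                    return int(i)
                return None
        return None

    # -- oracle tables -----------------------------------------------------
    def cell_frame_table(self, complete_only: bool = True) -> pd.DataFrame:
        """Tidy per-cell-per-frame table (the imaging pipeline's oracle twin)."""
        times = self.frame_times()
        rows = []
        for c in self.cells.values():
            if complete_only and not self.complete(c):
                continue
            sept = self.septation_frame(c)
            for i in self.frames_of(c):
                t = times[i]
                foci = self.foci(c, t, frame=int(i))
                rows.append(dict(cell=c.id, frame=int(i), time=t,
                                 age_frac=(t - c.birth_time) / c.gen_time,
                                 length=self.length(c, t),
                                 n_foci=len(foci),
                                 constricting=t >= c.t_con_abs - 1e-9,
                                 sept_frame=sept))
        return pd.DataFrame(rows, columns=["cell", "frame", "time", "age_frac",
                                           "length", "n_foci", "constricting",
                                           "sept_frame"])

    def foci_table(self, complete_only: bool = True) -> pd.DataFrame:
        """One row per focus per frame; x is oriented old pole -> new pole."""
        times = self.frame_times()
        rows = []
        for c in self.cells.values():
            if complete_only and not self.complete(c):
                continue
            for i in self.frames_of(c):
                for x in self.foci(c, times[i], frame=int(i)):
                    rows.append(dict(cell=c.id, frame=int(i), x=x, d=abs(x - 0.5)))
        return pd.DataFrame(rows, columns=["cell", "frame", "x", "d"])


def _make_cell(cfg: SimulationConfig, seed: int, cell_id: str, parent: str | None,
               birth_time: float, birth_length: float, orient: int,
               born_foci: tuple[float, ...]) -> SimCell:
    rng = _stream(seed, "cell", cell_id)
    tf = 1.0 + cfg.generation_time_cv * rng.standard_normal()
    gen_time = cfg.generation_time * max(0.2, tf)
    t_sep = _truncnorm01(rng, cfg.t_sep_mean, cfg.t_sep_sd)
    t_con = _truncnorm01(rng, cfg.t_con_mean, cfg.t_con_sd)
    # late-split draws are made unconditionally so that toggling overlap_rounds
    # does not reshuffle other quantities
    do_split = rng.random(2) < cfg.late_split_prob
    ts = np.array([_truncnorm01(rng, cfg.late_split_mean, cfg.late_split_sd)
                   for _ in range(2)])
    ts = np.where(do_split, np.maximum(ts, t_sep + 0.02), np.nan)
    return SimCell(id=cell_id, parent=parent, birth_time=birth_time,
                   gen_time=gen_time, birth_length=birth_length,
                   t_sep=t_sep, t_con=t_con, orient=orient,
                   born_foci=born_foci, late_splits=tuple(ts))


def _partition_foci(truth: GroundTruth, cell: SimCell) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Split the mother's division-time foci between her daughters.

    A focus at internal position x < 0.5 goes to the old-pole-side daughter at
    2x; a focus at x >= 0.5 goes to the new-pole-side daughter at 2(1 - x),
    so both daughters are again expressed old pole -> new pole.
    """
    phi = min((cell.division_time - cell.birth_time) / cell.gen_time, 2.0)
    pos = truth._foci_positions(cell, phi)
    old_side = tuple(sorted(2.0 * x for x in pos if x < 0.5))
    new_side = tuple(sorted(2.0 * (1.0 - x) for x in pos if x >= 0.5))
    return (old_side or (0.5,), new_side or (0.5,))


def simulate_population(
    config: SimulationConfig,
    duration: float,
    seed: int | None = None,
    *,
    n_founders: int = 1,
    founder_age: float = 0.0,
) -> tuple[list[SimCell], GroundTruth]:
    """Simulate a population for *duration* minutes.

    Founders start at cycle fraction ``founder_age`` (0 = just born).  Returns
    the founder cells (roots of the genealogy) and the full :class:`GroundTruth`.
    Deterministic given the seed.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if duration < config.generation_time:
        raise ValueError("duration must cover at least one generation time")
    if not 0.0 <= founder_age < 1.0:
        raise ValueError("founder_age must lie in [0, 1)")
    seed = config.seed if seed is None else int(seed)

    cells: dict[str, SimCell] = {}
    roots: list[str] = []
    truth = GroundTruth(config, duration, seed, cells, roots)

    queue: list[SimCell] = []
    for k in range(n_founders):
        rng = _stream(seed, "founder", k)
        bl = config.birth_length_mean * max(0.3, 1.0 + config.birth_length_cv
                                            * rng.standard_normal())
        born = (config.birth_focus_position,)
        if config.overlap_rounds and rng.random() < 0.5:
            born = (0.4, 0.6)
        c = _make_cell(config, seed, str(k), None, 0.0, bl, +1, born)
        # founders may start mid-cycle: shift birth into the past
        if founder_age > 0:
            c.birth_time = -founder_age * c.gen_time
        cells[c.id] = c
        roots.append(c.id)
        queue.append(c)

    while queue:
        c = queue.pop()
        if not config.scission_enabled:
            continue
        td = c.birth_time + c.gen_time
        c.division_time = td
        if td > duration + 1e-9:
            continue
        l_half = truth.length(c, td) / 2.0
        f_old, f_new = _partition_foci(truth, c)
        d_old = _make_cell(config, seed, c.id + ".O", c.id, td, l_half,
                           c.orient, f_old)
        d_new = _make_cell(config, seed, c.id + ".N", c.id, td, l_half,
                           -c.orient, f_new)
        c.daughters = (d_old.id, d_new.id)
        cells[d_old.id] = d_old
        cells[d_new.id] = d_new
        queue.extend([d_old, d_new])

    return [cells[r] for r in roots], truth


# ---------------------------------------------------------------------------
# snapshots

@dataclass
class CellObservation:
    """One cell from a snapshot: pole identity discarded by a random flip."""

    cell: str
    time: float
    length: float
    foci: tuple[float, ...]
    constricting: bool
    flipped: bool = False

    @property
    def n_foci(self) -> int:
        return len(self.foci)


def snapshot_sample(truth: GroundTruth, time: float, seed: int = 0) -> list[CellObservation]:
    """Sample every live cell at *time*, with seeded random orientation flips."""
    if not 0.0 <= time <= truth.duration:
        raise ValueError("snapshot time outside the simulated window")
    times = truth.frame_times()
    frame = int(np.argmin(np.abs(times - time)))
    out = []
    for c in sorted(truth.cells_alive(time), key=lambda c: c.id):
        pos = truth.foci(c, time, frame=frame)
        flip = bool(_stream(seed, "flip", c.id).random() < 0.5)
        if flip:
            pos = [1.0 - x for x in pos]
        out.append(CellObservation(cell=c.id, time=time,
                                   length=truth.length(c, time),
                                   foci=tuple(sorted(pos)),
                                   constricting=time >= c.t_con_abs - 1e-9,
                                   flipped=flip))
    return out


# ---------------------------------------------------------------------------
# plating assay

def simulate_plating(pcfg: PlatingSimConfig, seed: int | None = None,
                     replicate: str | int = 0) -> PlatingCounts:
    """Simulate one cassette-excision plating experiment.

    Each founder is tracked as an independent line of descent that excises the
    cassette at each exponential-phase division with probability
    ``f_indep (+ f_dep if recA+)``; lag and stationary phases contribute no
    divisions and hence no recombination.  Colony counts at both time points
    are binomial samples of the population's non-recombined fraction.
    """
    if pcfg.colonies_sampled == 0:
        raise ValueError("colonies_sampled must be > 0")
    if pcfg.initial_cells == 0:
        raise ValueError("initial_cells must be > 0")
    rng = np.random.default_rng(pcfg.seed if seed is None else seed)
    f = pcfg.f_total
    n = pcfg.n_generations_exp
    if f <= 0:
        nonrec_frac = 1.0
    elif f >= 1.0:
        nonrec_frac = 0.0 if n >= 1 else 1.0
    else:
        # division index of the first excision event, geometric with rate f
        first = rng.geometric(f, size=pcfg.initial_cells)
        nonrec_frac = float(np.mean(first > n))
    m = pcfg.colonies_sampled
    blue_i = m                                   # cultures start fully non-recombined
    blue_f = int(rng.binomial(m, nonrec_frac))
    Ni = float(pcfg.initial_cells)
    Nf = Ni * 2.0 ** n
    return PlatingCounts(
        Ni=Ni, Nf=Nf,
        Ri=blue_i / m, Rf=blue_f / m,
        replicate=replicate,
        condition="recA+" if pcfg.recA_plus else "recA-",
        colonies_total_i=m, colonies_white_i=m - blue_i,
        colonies_total_f=m, colonies_white_f=m - blue_f,
    )


def simulate_plating_replicates(pcfg: PlatingSimConfig, n_replicates: int,
                                seed: int | None = None) -> list[PlatingCounts]:
    """Independent replicate experiments with per-replicate derived seeds."""
    base = pcfg.seed if seed is None else seed
    return [simulate_plating(pcfg, seed=int(_stream(base, "plate", r).integers(2 ** 31)),
                             replicate=r)
            for r in range(n_replicates)]
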