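"""Simulation configuration and growth-condition presets.

The simulator emulates exponentially elongating rod-shaped bacteria carrying a
single fluorescently tagged chromosomal locus in the replication-terminus
region.  Two cell-cycle events are drawn per cell as fractions of its cycle:

``t_sep``
    the moment the sister copies of the tagged locus visibly separate, and
``t_con``
    the moment septum constriction first becomes optically detectable.

The presets encode the qualitative regimes observed for *E. coli* and
*V. cholerae* under fast and slow growth: in slow growth the sister termini
separate at (or just after) the onset of constriction at ~80% of the cycle,
whereas in fast growth they separate around 40% of the cycle, well before the
septum becomes visible, and late extra duplications (overlapping replication
rounds) produce cells with 3-4 foci near division.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the single-cell lineage simulator and movie renderer.

    Times are in minutes, lengths in micrometres, cell-cycle event timings in
    fractions of the cell cycle (0 = birth, 1 = division).
    """

    # growth / geometry
    growth_rate: float | None = None        # 1/min; ln(2)/generation_time when None
    birth_length_mean: float = 2.5          # um
    birth_length_cv: float = 0.10
    generation_time: float = 92.0           # min
    generation_time_cv: float = 0.08
    cell_width: float = 1.0                 # um (rod diameter)

    # cell-cycle event timing (cycle fractions, truncated normal on [0, 1])
    t_sep_mean: float = 0.82
    t_sep_sd: float = 0.05
    t_con_mean: float = 0.78
    t_con_sd: float = 0.05

    # focus choreography
    post_sep_targets: tuple[float, float] = (0.25, 0.75)
    relocation_time: float = 0.0            # min; 0 = jump to targets at separation
    focus_jitter_sd: float = 0.01           # cell-length fractions, per frame
    birth_focus_position: float = 0.5       # relative coordinate, old pole = 0
    midcell_arrival: float = 0.3            # cycle fraction at which the focus reaches mid-cell

    # overlapping replication rounds (fast growth): cells may be born with two
    # foci and post-separation foci may split again late in the cycle
    overlap_rounds: bool = False
    late_split_mean: float = 0.85
    late_split_sd: float = 0.04
    late_split_prob: float = 0.6
    late_split_offset: float = 0.06         # relative half-separation of a late pair

    scission_enabled: bool = True           # False = filament (no-division) mode

    # imaging
    frame_interval: float = 4.0             # min
    pixel_size: float = 0.065               # um/px
    psf_sigma: float = 0.1                  # um
    background: float = 100.0               # camera offset, both channels
    spot_amplitude: float = 400.0
    noise_sd: float = 20.0                  # additive Gaussian, per pixel per plane
    bf_contrast: float = 150.0              # bright-field body contrast at full defocus
    n_stack_planes: int = 32                # bright-field planes spanning +-stack_halfspan
    stack_halfspan: float = 1.6             # um defocus half-span
    septum_depth0: float = 0.45             # dark-line depth at constriction onset
    septum_depth_max: float = 0.65
    septum_ramp_time: float = 10.0          # min to ramp depth0 -> depth_max
    septum_line_sigma: float = 1.5          # px, transverse dark-line width

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("t_sep_mean", "t_con_mean", "birth_focus_position",
                     "midcell_arrival", "late_split_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("t_sep_sd", "t_con_sd", "birth_length_cv", "generation_time_cv",
                     "focus_jitter_sd", "late_split_sd", "noise_sd", "relocation_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.generation_time <= 0 or self.birth_length_mean <= 0:
            raise ValueError("generation_time and birth_length_mean must be > 0")
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("pixel_size and psf_sigma must be > 0")
        if self.n_stack_planes < 2:
            raise ValueError("n_stack_planes must be >= 2")
        lo, hi = self.post_sep_targets
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("post_sep_targets must be an increasing pair in [0, 1]")

    @property
    def elongation_rate(self) -> float:
        """Exponential elongation rate (1/min)."""
        if self.growth_rate is not None:
            return self.growth_rate
        return math.log(2.0) / self.generation_time

    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.pixel_size


# Growth-condition presets.  Generation times follow the measured doubling
# times in the corresponding media; event timings follow the reported cycle
# fractions (separation at ~80% in slow growth, ~40% in fast growth for
# E. coli; constriction onset at ~60% in fast growth).  Slow presets place the
# birth focus near the new pole and the post-separation targets close to
# mid-cell so that the partitioning of a mother's foci reproduces the
# new-pole-proximal birth position of her daughters.
_PRESETS: dict[str, dict] = {
    "Ec-slow": dict(
        generation_time=92.0, frame_interval=4.0,
        t_sep_mean=0.82, t_con_mean=0.78,
        birth_focus_position=0.75, post_sep_targets=(0.375, 0.625),
        midcell_arrival=0.3, overlap_rounds=False,
    ),
    "Ec-fast": dict(
        generation_time=40.0, frame_interval=2.0,
        t_sep_mean=0.40, t_con_mean=0.62,
        birth_focus_position=0.5, post_sep_targets=(0.25, 0.75),
        midcell_arrival=0.15, overlap_rounds=True,
        birth_length_mean=3.0,
    ),
    "Vc-slow": dict(
        generation_time=80.0, frame_interval=4.0,
        t_sep_mean=0.85, t_con_mean=0.80,
        birth_focus_position=0.84, post_sep_targets=(0.42, 0.58),
        midcell_arrival=0.4, overlap_rounds=False,
        birth_length_mean=2.2,
    ),
    "Vc-fast": dict(
        generation_time=23.0, frame_interval=2.0,
        t_sep_mean=0.82, t_con_mean=0.72,
        birth_focus_position=0.84, post_sep_targets=(0.42, 0.58),
        midcell_arrival=0.4, overlap_rounds=False,
        birth_length_mean=2.2,
    ),
    # matP deletion: separation uncoupled from constriction (fast growth values)
    "dMatP": dict(
        generation_time=44.0, frame_interval=2.0,
        t_sep_mean=0.20, t_con_mean=0.60,
        birth_focus_position=0.5, post_sep_targets=(0.25, 0.75),
        midcell_arrival=0.1, overlap_rounds=True,
        birth_length_mean=3.0,
    ),
    # translocation-dead FtsK in slow growth: separation only at ~90% of the
    # cycle while constriction is visible from ~70%
    "ftsK-ATP-": dict(
        generation_time=108.0, frame_interval=4.0,
        t_sep_mean=0.90, t_con_mean=0.70,
        birth_focus_position=0.75, post_sep_targets=(0.375, 0.625),
        midcell_arrival=0.3, overlap_rounds=False,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, **overrides) -> SimulationConfig:
    """Return a fully populated :class:`SimulationConfig` for a named preset."""
    try:
        kwargs = dict(_PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; known: {', '.join(PRESET_NAMES)}") from None
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def zero_noise(cfg: SimulationConfig) -> SimulationConfig:
    """A copy of *cfg* with all imaging noise and focus jitter removed."""
    return replace(cfg, noise_sd=0.0, focus_jitter_sd=0.0)


@dataclass(frozen=True)
class PlatingSimConfig:
    """Parameters of the cassette-excision plating-assay simulator.

    ``f_indep`` and ``f_dep`` are per-division excision probabilities: the
    recA-independent component is always active, the recA-dependent component
    only when ``recA_plus``.  Lag and stationary phases contribute no divisions
    and therefore no recombination.
    """

    f_indep: float = 0.01
    f_dep: float = 0.04
    recA_plus: bool = True
    n_generations_exp: int = 20
    lag_divisions: int = 0
    stationary_divisions: int = 0
    initial_cells: int = 10_000
    colonies_sampled: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_indep + self.f_dep <= 1.0:
            raise ValueError("f_indep + f_dep must lie in [0, 1]")
        if min(self.f_indep, self.f_dep) < 0:
            raise ValueError("excision probabilities must be >= 0")
        for name in ("n_generations_exp", "lag_divisions", "stationary_divisions",
                     "initial_cells", "colonies_sampled"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def f_total(self) -> float:
        return self.f_indep + (self.f_dep if self.recA_plus else 0.0)
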