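"""Cassette-excision frequency estimation from plating assays.

A reporter cassette carrying two *dif* recombination sites flanking part of
*lacZ* is excised by XerCD recombination, turning blue (non-recombined)
colonies white on X-Gal plates.  Over a growth experiment with ``n`` divisions
the non-recombined fraction decays geometrically, so the per-generation
excision probability ``f`` follows from the initial and final non-recombined
ratios ``Ri`` and ``Rf``::

    Rf / Ri = (1 - f)**n          =>          f = 1 - exp(ln(Rf / Ri) / n)

with ``n = ln(Nf / Ni) / ln 2`` deduced from the initial and final cell
densities.  ``Ri`` is normally 1 (cultures start fully non-recombined) and the
estimate is most reliable while ``Rf`` stays in the 10-90% window.

The recA-dependency of excision, the fraction of the excision rate that is
attributable to homologous-recombination-generated chromosome dimers, is
``1 - f(recA-) / f(recA+)``.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayWarning",
    "PlatingCounts",
    "ExcisionEstimate",
    "count_divisions",
    "excision_frequency",
    "predict_final_ratio",
    "reca_dependency",
    "estimate_from_counts",
    "bootstrap_ci",
    "read_counts_csv",
    "analyze_counts_table",
]

RF_WINDOW = (0.10, 0.90)


class AssayWarning(UserWarning):
    """Non-fatal diagnostic raised by the assay estimators."""


@dataclass
class PlatingCounts:
    """Cell and colony counts from one cassette-excision experiment.

    ``Ri``/``Rf`` are the non-recombined (blue) colony fractions at the start
    and end of the experiment.  Raw colony counts are optional; when present
    they are the source of the ratios.
    """

    Ni: float
    Nf: float
    Ri: float = 1.0
    Rf: float = 1.0
    replicate: str | int = 0
    condition: str = ""
    colonies_total_i: int | None = None
    colonies_white_i: int | None = None
    colonies_total_f: int | None = None
    colonies_white_f: int | None = None

    def __post_init__(self) -> None:
        if self.Ni <= 0 or self.Nf <= 0:
            raise ValueError("cell counts Ni, Nf must be > 0")
        if not (0.0 < self.Ri <= 1.0) or not (0.0 <= self.Rf <= 1.0):
            raise ValueError("ratios must satisfy 0 < Ri <= 1 and 0 <= Rf <= 1")


@dataclass
class ExcisionEstimate:
    """Per-generation excision frequency with optional bootstrap bounds."""

    f: float
    n: float
    ci_low: float | None = None
    ci_high: float | None = None
    warnings: list[str] = field(default_factory=list)


def count_divisions(Ni: float, Nf: float, *, allow_shrink: bool = False) -> float:
    """Number of divisions from initial/final cell densities, ln(Nf/Ni)/ln 2.

    A shrinking culture (``Nf < Ni``) yields a negative division count, which
    is an error unless explicitly allowed.
    """
    if Ni <= 0 or Nf <= 0:
        raise ValueError("cell counts must be > 0")
    n = math.log(Nf / Ni) / math.log(2.0)
    if n < 0 and not allow_shrink:
        raise ValueError(
            f"Nf < Ni gives a negative division count (n={n:.3g}); "
            "pass allow_shrink=True for a shrinking culture"
        )
    return n


def excision_frequency(Rf: float, n: float, Ri: float = 1.0) -> float:
    """Per-generation excision probability f = 1 - exp(ln(Rf/Ri)/n).

    Emits an :class:`AssayWarning` when ``Rf`` falls outside the 10-90% window
    in which the readout is best monitored.
    """
    if n <= 0:
        raise ValueError("number of divisions n must be > 0")
    if not (0.0 < Rf <= Ri <= 1.0):
        raise ValueError(
            f"need 0 < Rf <= Ri <= 1; got Rf={Rf}, Ri={Ri}. "
            "Rf > Ri would imply a negative apparent excision frequency."
        )
    if not RF_WINDOW[0] <= Rf <= RF_WINDOW[1]:
        _warnings.warn(
            f"Rf={Rf:.3g} outside the {RF_WINDOW[0]:.0%}-{RF_WINDOW[1]:.0%} window; "
            "the excision-frequency estimate is poorly conditioned",
            AssayWarning,
            stacklevel=2,
        )
    return 1.0 - math.exp(math.log(Rf / Ri) / n)


def predict_final_ratio(f: float, n: float) -> float:
    """Expected non-recombined fraction after n divisions, (1 - f)**n."""
    if not 0.0 <= f < 1.0:
        raise ValueError("f must lie in [0, 1)")
    if n < 0:
        raise ValueError("n must be >= 0")
    return (1.0 - f) ** n


def reca_dependency(f_plus: float, f_minus: float) -> float:
    """Fraction of the excision rate linked to recA, 1 - f(recA-)/f(recA+).

    Negative values (recA- rate exceeding recA+) are reported verbatim with a
    warning, never clamped.
    """
    if f_plus <= 0:
        raise ValueError("f_plus must be > 0")
    if f_minus < 0:
        raise ValueError("f_minus must be >= 0")
    dep = 1.0 - f_minus / f_plus
    if dep < 0:
        _warnings.warn(
            f"negative recA-dependency ({dep:.3g}): recA- excision rate exceeds recA+",
            AssayWarning,
            stacklevel=2,
        )
    return dep


def estimate_from_counts(pc: PlatingCounts) -> ExcisionEstimate:
    """Plug-in estimate (f, n) from a single experiment's counts."""
    notes: list[str] = []
    n = count_divisions(pc.Ni, pc.Nf)
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always", AssayWarning)
        f = excision_frequency(pc.Rf, n, pc.Ri)
    notes.extend(str(w.message) for w in caught)
    return ExcisionEstimate(f=f, n=n, warnings=notes)


def _plugin_fs(replicates: Sequence[PlatingCounts]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    ests = [estimate_from_counts(pc) for pc in replicates]
    notes = [m for e in ests for m in e.warnings]
    return (np.array([e.f for e in ests]),
            np.array([e.n for e in ests]),
            notes)


def bootstrap_ci(
    replicates: Sequence[PlatingCounts],
    n_boot: int = 2000,
    seed: int = 0,
    *,
    pooled: bool = False,
    alpha: float = 0.05,
) -> ExcisionEstimate:
    """Percentile bootstrap over experimental replicates of the plug-in f.

    By default f is computed per replicate and the replicate mean is
    bootstrapped (matching the per-experiment averaging of multi-replicate
    assays).  With ``pooled=True`` the replicate Rf values are averaged first
    and a single f computed per bootstrap resample.
    """
    if len(replicates) < 2:
        raise ValueError("bootstrap requires at least 2 replicates")
    fs, ns, notes = _plugin_fs(replicates)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(replicates), size=(n_boot, len(replicates)))
    if pooled:
        rfs = np.array([pc.Rf for pc in replicates])
        ris = np.array([pc.Ri for pc in replicates])
        boot = 1.0 - np.exp(np.log(rfs[idx].mean(axis=1) / ris[idx].mean(axis=1))
                            / ns[idx].mean(axis=1))
        point = 1.0 - math.exp(math.log(rfs.mean() / ris.mean()) / ns.mean())
    else:
        boot = fs[idx].mean(axis=1)
        point = float(fs.mean())
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    return ExcisionEstimate(f=point, n=float(ns.mean()),
                            ci_low=float(lo), ci_high=float(hi), warnings=notes)


# ---------------------------------------------------------------------------
# tabular I/O

_CSV_COLUMNS = ("replicate", "condition", "Ni", "Nf",
                "colonies_total_i", "colonies_white_i",
                "colonies_total_f", "colonies_white_f")


def read_counts_csv(path) -> list[PlatingCounts]:
    """Read a plating-count table (one row per replicate) into PlatingCounts.

    Expected columns: replicate, condition, Ni, Nf, colonies_total_i,
    colonies_white_i, colonies_total_f, colonies_white_f.  Blue (non-recombined)
    fractions are derived as (total - white) / total.
    """
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts CSV missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        ti, wi = int(row.colonies_total_i), int(row.colonies_white_i)
        tf, wf = int(row.colonies_total_f), int(row.colonies_white_f)
        if ti <= 0 or tf <= 0:
            raise ValueError("colony totals must be > 0")
        out.append(PlatingCounts(
            Ni=float(row.Ni), Nf=float(row.Nf),
            Ri=(ti - wi) / ti, Rf=(tf - wf) / tf,
            replicate=row.replicate, condition=str(row.condition),
            colonies_total_i=ti, colonies_white_i=wi,
            colonies_total_f=tf, colonies_white_f=wf,
        ))
    return out


def analyze_counts_table(
    replicates: Iterable[PlatingCounts],
    *,
    n_boot: int = 2000,
    seed: int = 0,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-condition excision estimates (replicate-averaged, with bootstrap CI).

    Returns one row per condition with columns f, n, ci_low, ci_high,
    n_replicates, warnings.  Conditions with a single replicate get no CI.
    """
    by_cond: dict[str, list[PlatingCounts]] = {}
    for pc in replicates:
        by_cond.setdefault(pc.condition, []).append(pc)
    rows = []
    for cond, pcs in by_cond.items():
        if len(pcs) >= 2:
            est = bootstrap_ci(pcs, n_boot=n_boot, seed=seed, pooled=pooled)
        else:
            est = estimate_from_counts(pcs[0])
        rows.append(dict(condition=cond, f=est.f, n=est.n,
                         ci_low=est.ci_low, ci_high=est.ci_high,
                         n_replicates=len(pcs),
                         warnings="; ".join(sorted(set(est.warnings)))))
    return pd.DataFrame(rows)
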