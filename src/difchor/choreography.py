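"""Per-cell cycle projections, consensus images and septation detection.

Each frame of a cell's life is reduced to a longitudinal profile (mean
intensity over transverse slices along the long axis), min-max normalised to
[0, 1].  Stacking the profiles of one complete cell cycle on a normalised
(cycle time x cell length) grid gives a per-cell kymograph, oriented old pole
-> new pole; averaging kymographs element-wise over many cells gives a
consensus image in which every cell cycle contributes equally.

Septation onset is detected from the shape-channel profiles as the first
frame in which a persistent local minimum in the central window of the cell
dips below a smooth baseline by a multiple of the robust noise scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imaging import CellRegion, PoleFrame

__all__ = [
    "LongAxisProfile",
    "Kymograph",
    "ConsensusImage",
    "SeptationCall",
    "long_axis_profile",
    "normalize_profile",
    "kymograph_from_profiles",
    "consensus_image",
    "classify_constriction",
    "detect_septation",
    "consensus_split_time",
    "consensus_septum_rows",
]

DETECTION_WINDOW = (0.35, 0.65)


@dataclass
class LongAxisProfile:
    """Mean transverse intensity along the cell length (old pole first when oriented)."""

    values: np.ndarray
    oriented: bool = False
    constant: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.values)


def long_axis_profile(
    image: np.ndarray,
    region: CellRegion,
    n_bins: int | None = 51,
    poles: PoleFrame | None = None,
    slice_px: float = 2.0,
) -> LongAxisProfile:
    """Partition the cell into *n_bins* transverse slices and average each.

    The slices span the cell from pole to pole: sub-pixel pole positions when
    *poles* is given, otherwise the mask extent.  ``n_bins=None`` picks the
    bin count adaptively so that each slice is about ``slice_px`` pixels long
    (short cells then keep enough pixels per slice for stable averages).
    Empty bins are interpolated from their neighbours.
    """
    if region.area == 0:
        raise ValueError("region of zero area")
    coords = region.coords().astype(float)
    vals = image[coords[:, 0].astype(int), coords[:, 1].astype(int)]
    if poles is not None:
        proj = (coords - poles.centroid) @ poles.axis
        lo, hi = poles.p0, poles.p1
    else:
        proj = (coords - region.centroid) @ region.axis
        lo, hi = proj.min(), proj.max()
    span = max(hi - lo, 1e-9)
    if n_bins is None:
        n_bins = max(8, int(round(span / slice_px)))
    which = np.clip(((proj - lo) / span * n_bins).astype(int), 0, n_bins - 1)
    sums = np.bincount(which, weights=vals, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    good = counts > 0
    centers = np.arange(n_bins, dtype=float)
    values = np.empty(n_bins)
    values[good] = sums[good] / counts[good]
    if not good.all():
        values = np.interp(centers, centers[good], values[good])
    return LongAxisProfile(values=values)


def normalize_profile(p: LongAxisProfile | np.ndarray) -> LongAxisProfile:
    """Min-max rescale to [0, 1]; a constant profile maps to zeros (flagged)."""
    values = p.values if isinstance(p, LongAxisProfile) else np.asarray(p, dtype=float)
    oriented = p.oriented if isinstance(p, LongAxisProfile) else False
    rng = values.max() - values.min()
    if rng < 1e-12:
        return LongAxisProfile(values=np.zeros_like(values), oriented=oriented,
                               constant=True)
    return LongAxisProfile(values=(values - values.min()) / rng, oriented=oriented)


@dataclass
class Kymograph:
    """Normalised (cycle time x cell length) matrix for one cell cycle.

    Rows run from birth (0) to division (1); columns from the old pole (0) to
    the new pole (1).  Every non-constant row has min 0 and max 1.
    """

    data: np.ndarray
    channel: str = "fluor"


@dataclass
class ConsensusImage:
    """Element-wise mean of per-cell kymographs; each cell contributes equally."""

    data: np.ndarray
    count: int
    channel: str = "fluor"


def _resample_rows(mat: np.ndarray, n_out: int) -> np.ndarray:
    n_in = mat.shape[0]
    if n_in == n_out:
        return mat
    src = np.linspace(0.0, 1.0, n_in)
    dst = np.linspace(0.0, 1.0, n_out)
    return np.stack([np.interp(dst, src, mat[:, j]) for j in range(mat.shape[1])], axis=1)


def _resample_cols(mat: np.ndarray, n_out: int) -> np.ndarray:
    return _resample_rows(mat.T, n_out).T


def kymograph_from_profiles(
    profiles: list[np.ndarray] | np.ndarray,
    grid: tuple[int, int] = (101, 101),
    channel: str = "fluor",
    flip: bool = False,
) -> Kymograph:
    """Build a kymograph from per-frame profiles of one complete cell cycle.

    Profiles must already run old pole -> new pole unless ``flip`` is set.
    Each profile is min-max normalised, resampled to the target grid by linear
    interpolation on both axes, and the rows are re-normalised.
    """
    mat = np.asarray([np.asarray(p, dtype=float) for p in profiles])
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need >= 2 frame profiles of equal length")
    if flip:
        mat = mat[:, ::-1]
    T, X = grid
    mat = np.stack([normalize_profile(row).values for row in mat])
    mat = _resample_cols(mat, X)
    mat = _resample_rows(mat, T)
    mat = np.stack([normalize_profile(row).values for row in mat])
    return Kymograph(data=mat, channel=channel)


def consensus_image(kymographs: list[Kymograph]) -> ConsensusImage:
    """Element-wise mean over identically gridded kymographs."""
    if not kymographs:
        raise ValueError("empty kymograph list")
    shapes = {k.data.shape for k in kymographs}
    if len(shapes) > 1:
        raise ValueError(f"grid mismatch between kymographs: {shapes}")
    data = np.mean([k.data for k in kymographs], axis=0)
    return ConsensusImage(data=data, count=len(kymographs),
                          channel=kymographs[0].channel)


# ---------------------------------------------------------------------------
# septation detection

@dataclass
class SeptationCall:
    """First detected constriction: frame index, relative position, dip depth."""

    frame: int
    position: float
    depth: float


def _dip_test(values: np.ndarray, window: tuple[float, float], k: float,
              min_depth_frac: float) -> tuple[bool, float, float]:
    """Robust baseline-dip test on one longitudinal profile.

    A quadratic baseline is fit to the central 60% of the profile; the deepest
    local minimum in the central *window* is located, the baseline and robust
    noise scale (1.4826 x MAD of the residuals) are re-estimated with the dip
    neighbourhood excluded, and a constriction is reported when the dip
    undercuts the baseline by >= k x that scale and by >= ``min_depth_frac``
    of the profile's dynamic range.
    """
    n = len(values)
    if n < 7:
        return False, math.nan, 0.0
    ci = np.arange(int(0.20 * n), int(math.ceil(0.80 * n)))
    x, y = ci.astype(float), values[ci]
    coef = np.polyfit(x, y, 2)
    resid = y - np.polyval(coef, x)
    wlo, whi = int(window[0] * n), int(math.ceil(window[1] * n))
    cand = [j for j in range(max(wlo, ci[0] + 1), min(whi, ci[-1]))
            if values[j] <= values[j - 1] and values[j] <= values[j + 1]]
    if not cand:
        return False, math.nan, 0.0
    dip = min(cand, key=lambda j: resid[j - ci[0]])
    keep = np.abs(ci - dip) > 2
    if keep.sum() >= 5:
        coef = np.polyfit(x[keep], y[keep], 2)
        resid = y - np.polyval(coef, x)
    scale = max(1.4826 * np.median(np.abs(resid[keep] - np.median(resid[keep]))),
                1e-9 * max(np.ptp(values), 1.0))
    depth = float(-resid[dip - ci[0]])
    pos = dip / (n - 1)
    ok = depth >= k * scale and depth >= min_depth_frac * max(np.ptp(values), 1e-12)
    return ok, float(pos), depth


def classify_constriction(
    profile: LongAxisProfile | np.ndarray,
    *,
    window: tuple[float, float] = DETECTION_WINDOW,
    k: float = 3.0,
    min_depth_frac: float = 0.20,
) -> tuple[bool, float, float]:
    """Single-profile constriction test (used for snapshots)."""
    values = profile.values if isinstance(profile, LongAxisProfile) else np.asarray(profile)
    return _dip_test(values, window, k, min_depth_frac)


def detect_septation(
    profiles: list[np.ndarray] | list[LongAxisProfile],
    *,
    window: tuple[float, float] = DETECTION_WINDOW,
    k: float = 3.0,
    min_depth_frac: float = 0.20,
    position_tol: float = 0.10,
) -> SeptationCall | None:
    """First frame of a persistent central dip across a cell's life, or None.

    A constriction is called at frame i when the dip test fires at frames i
    and i+1 at consistent relative positions (within ``position_tol``): a real
    septum is stationary along the cell, so demanding positional persistence
    suppresses single-frame noise dips, which land at random positions.
    """
    if len(profiles) < 3:
        raise ValueError("need >= 3 frames to call septation")
    hits = [classify_constriction(p, window=window, k=k,
                                  min_depth_frac=min_depth_frac)
            for p in profiles]
    for i in range(len(hits) - 1):
        ok, pos, depth = hits[i]
        ok2, pos2, _ = hits[i + 1]
        if ok and ok2 and abs(pos - pos2) <= position_tol:
            return SeptationCall(frame=i, position=pos, depth=depth)
    return None


# ---------------------------------------------------------------------------
# consensus-image summaries

def consensus_split_time(consensus: ConsensusImage, band: float = 0.04) -> float:
    """Cycle fraction at which the mid-cell fluorescence ridge splits.

    In a consensus image of per-row-normalised kymographs the mean intensity
    of the central column band tracks the fraction of cells whose sister foci
    have not yet separated; its half-way crossing after the plateau therefore
    estimates the population's median separation time.
    """
    T, X = consensus.data.shape
    lo = max(0, int((0.5 - band) * X))
    hi = min(X, int(math.ceil((0.5 + band) * X)))
    c = consensus.data[:, lo:hi].mean(axis=1)
    if len(c) >= 3:                      # light smoothing against row noise
        c = np.convolve(c, np.ones(3) / 3.0, mode="same")
        c[0], c[-1] = c[1], c[-2]
    peak_row = int(np.argmax(c))
    floor = c[peak_row:].min()
    half = floor + 0.5 * (c[peak_row] - floor)
    rows = np.arange(T) / (T - 1)
    for i in range(peak_row + 1, T):
        if c[i] < half:
            f = (c[i - 1] - half) / (c[i - 1] - c[i])
            return float(rows[i - 1] + f * (rows[i] - rows[i - 1]))
    return 1.0


def consensus_septum_rows(consensus: ConsensusImage, *, k: float = 3.0) -> np.ndarray:
    """Row indices of a shape-channel consensus showing a central septal dip."""
    hits = [classify_constriction(row, k=k)[0] for row in consensus.data]
    return np.nonzero(hits)[0]
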