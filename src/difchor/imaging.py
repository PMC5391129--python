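"""Shape reconstruction, cell segmentation and lineage tracking.

The bright-field defocus stack is collapsed into a single "shape image" by a
per-pixel projection statistic (standard deviation by default): the cell-body
contrast flips sign through focus, so pixels inside cells vary strongly across
the stack while background pixels do not.  Septa appear as transverse dark
lines in the shape image.

Segmentation is a conventional threshold + morphology + connected-components
pass, deliberately conservative about splitting touching objects: a
one-to-two event during tracking is only accepted as a cell division once the
two candidate daughters stay apart (gap above a pixel threshold) for two
consecutive frames.  After a confirmed division the new pole of each daughter
is the end adjacent to its sibling, which fixes the old-pole -> new-pole
orientation of the whole subsequent cell cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import closing as sk_closing, dilation as sk_dilation, disk

__all__ = [
    "ShapeImage",
    "CellRegion",
    "PoleFrame",
    "TrackedCell",
    "reconstruct_shape_image",
    "segment_cells",
    "subpixel_poles",
    "track_and_genealogy",
]


@dataclass
class ShapeImage:
    """2-D cell-shape reconstruction from a bright-field stack."""

    data: np.ndarray
    pixel_size: float
    provenance: dict = field(default_factory=dict)


def reconstruct_shape_image(stack, pixel_size: float = 1.0, method: str = "std") -> ShapeImage:
    """Collapse a defocus stack into a shape image.

    ``method`` is the per-pixel projection statistic: ``std`` (default) or
    ``range`` (max - min).  Both make cell bodies bright against background
    and preserve the septal dark line.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a stack of >= 2 equally sized planes")
    if method == "std":
        data = stack.std(axis=0)
    elif method == "range":
        data = stack.max(axis=0) - stack.min(axis=0)
    else:
        raise ValueError(f"unknown projection method {method!r}")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in shape image")
    return ShapeImage(data=data, pixel_size=pixel_size,
                      provenance=dict(method=method, n_planes=stack.shape[0]))


@dataclass
class CellRegion:
    """One segmented cell in one frame (0-based pixel coordinates, origin top-left)."""

    frame: int
    label: int
    slice_: tuple[slice, slice]
    mask: np.ndarray                 # local boolean mask within slice_
    image_shape: tuple[int, int]
    centroid: np.ndarray             # (row, col)
    axis: np.ndarray                 # unit vector (row, col) along the long axis
    length_um: float
    pixel_size: float

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def coords(self) -> np.ndarray:
        rr, cc = np.nonzero(self.mask)
        return np.column_stack([rr + self.slice_[0].start, cc + self.slice_[1].start])

    def full_mask(self) -> np.ndarray:
        m = np.zeros(self.image_shape, dtype=bool)
        m[self.slice_][self.mask] = True
        return m

    def overlap(self, other: "CellRegion") -> int:
        return int((self.full_mask() & other.full_mask()).sum())


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    cov = c.T @ c / max(len(c), 1)
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    # deterministic sign: dominant component positive
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return axis


def segment_cells(
    shape: ShapeImage,
    *,
    threshold: float | None = None,
    closing_radius: int = 2,
    min_area_um2: float = 0.8,
) -> list[CellRegion]:
    """Threshold (Otsu default) + closing + connected components.

    Returns an empty list (not an error) for a blank image.  The closing step
    bridges the thin septal dark line so that a constricting cell stays a
    single region until actual scission separates the daughters.
    """
    data = shape.data
    if shape.pixel_size <= 0:
        raise ValueError("shape image must carry a calibrated pixel size")
    if np.ptp(data) < 1e-12:
        return []
    thr = threshold_otsu(data) if threshold is None else threshold
    mask = data > thr
    if not mask.any() or mask.all():
        return []
    if closing_radius > 0:
        mask = sk_closing(mask, disk(closing_radius))
    min_px = max(1, int(round(min_area_um2 / shape.pixel_size ** 2)))
    lbl = sk_label(mask)
    regions: list[CellRegion] = []
    for k in range(1, lbl.max() + 1):
        rr, cc = np.nonzero(lbl == k)
        if len(rr) < min_px:
            continue
        sl = (slice(rr.min(), rr.max() + 1), slice(cc.min(), cc.max() + 1))
        local = lbl[sl] == k
        coords = np.column_stack([rr, cc]).astype(float)
        axis = _principal_axis(coords)
        proj = coords @ axis
        length = (proj.max() - proj.min() + 1.0) * shape.pixel_size
        regions.append(CellRegion(
            frame=0, label=k, slice_=sl, mask=local,
            image_shape=data.shape,
            centroid=coords.mean(axis=0), axis=axis,
            length_um=float(length), pixel_size=shape.pixel_size,
        ))
    return regions


@dataclass
class PoleFrame:
    """Sub-pixel pole positions of one cell in one frame.

    ``p0``/``p1`` are projection coordinates (pixels) of the two cell ends
    along ``axis`` relative to ``centroid``; relative long-axis coordinates
    follow as (projection - p0) / (p1 - p0).
    """

    centroid: np.ndarray
    axis: np.ndarray
    p0: float
    p1: float

    @property
    def length_px(self) -> float:
        return self.p1 - self.p0

    def rel(self, point_rc) -> float:
        proj = float((np.asarray(point_rc, dtype=float) - self.centroid) @ self.axis)
        return (proj - self.p0) / (self.p1 - self.p0)


def _half_crossing(profile: np.ndarray, centers: np.ndarray, baseline: float,
                   plateau: float, from_left: bool) -> float:
    half = baseline + 0.5 * (plateau - baseline)
    idx = range(len(profile)) if from_left else range(len(profile) - 1, -1, -1)
    prev = None
    for i in idx:
        if profile[i] >= half:
            if prev is None:
                return float(centers[i])
            f = (half - profile[prev]) / (profile[i] - profile[prev])
            return float(centers[prev] + f * (centers[i] - centers[prev]))
        prev = i
    return float(centers[0] if from_left else centers[-1])


def _sum_profile(image: np.ndarray, region: CellRegion, pad: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Transverse-sum intensity profile along the long axis (1 px bins)."""
    dil = sk_dilation(region.full_mask(), disk(pad))
    rr, cc = np.nonzero(dil)
    coords = np.column_stack([rr, cc]).astype(float)
    proj = (coords - region.centroid) @ region.axis
    vals = image[rr, cc]
    edges = np.arange(math.floor(proj.min()), math.ceil(proj.max()) + 1.0)
    which = np.clip(np.digitize(proj, edges) - 1, 0, len(edges) - 2)
    sums = np.bincount(which, weights=vals, minlength=len(edges) - 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, sums


def subpixel_poles(image: np.ndarray, region: CellRegion, pad: int = 4) -> PoleFrame:
    """Locate the two cell poles at sub-pixel precision by a capsule fit.

    The transverse-sum longitudinal profile of a rod with hemispherical caps
    is proportional to the chord length of the capsule, so the profile is fit
    with a Gaussian-blurred chord model (offset, amplitude, two pole
    positions, cap radius, blur width).  Fitting the cap shape explicitly
    avoids the systematic inward bias that plain half-maximum crossings of
    transverse-averaged profiles suffer at rounded cell ends.  Falls back to
    half-maximum crossings if the fit fails.
    """
    from scipy.ndimage import gaussian_filter1d
    from scipy.optimize import least_squares

    centers, sums = _sum_profile(image, region, pad)
    lo, hi = centers[0], centers[-1]

    def model(p):
        off, amp, x0, x1, r, sig = p
        mid, half_body = (x0 + x1) / 2.0, np.maximum((x1 - x0) / 2.0 - r, 0.0)
        u = np.maximum(np.abs(centers - mid) - half_body, 0.0)
        chord = 2.0 * np.sqrt(np.maximum(r * r - u * u, 0.0))
        return off + amp * gaussian_filter1d(chord, max(sig, 0.3))

    r0 = max(2.5, min(region.mask.shape) / 2.0 - 1.0)
    p_init = np.array([float(sums.min()),
                       max((sums.max() - sums.min()) / (2.0 * r0), 1e-6),
                       lo + pad, hi - pad, r0, 1.5])
    try:
        res = least_squares(lambda p: model(p) - sums, p_init,
                            bounds=([-np.inf, 0.0, lo, lo, 1.5, 0.3],
                                    [np.inf, np.inf, hi, hi, 15.0, 4.0]),
                            xtol=1e-7, max_nfev=100)
        _, _, x0, x1, _, _ = res.x
        p0, p1 = (x0, x1) if x1 > x0 else (x1, x0)
        if p1 - p0 < 3.0:
            raise RuntimeError("degenerate capsule fit")
    except Exception:
        profile = sums / max(sums.max(), 1e-12)
        baseline = min(profile[0], profile[-1])
        plateau = np.median(profile[profile >= np.percentile(profile, 60)])
        p0 = _half_crossing(profile, centers, baseline, plateau, from_left=True)
        p1 = _half_crossing(profile, centers, baseline, plateau, from_left=False)
        if p1 <= p0:
            p0, p1 = lo, hi
    return PoleFrame(centroid=region.centroid, axis=region.axis,
                     p0=float(p0), p1=float(p1))


# ---------------------------------------------------------------------------
# tracking

@dataclass
class TrackedCell:
    """One tracked cell: its per-frame regions plus genealogy and polarity."""

    tid: int
    mother: int | None = None
    daughters: tuple[int, int] | None = None
    frames: list[int] = field(default_factory=list)
    regions: list[CellRegion] = field(default_factory=list)
    new_pole_at_max: bool | None = None   # new pole at the max-projection end?
    division_frame: int | None = None     # first frame of the daughters
    flags: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        """Observed from birth to own (confirmed) division."""
        return (self.mother is not None and self.daughters is not None
                and len(self.frames) >= 3)

    def region_at(self, frame: int) -> CellRegion:
        return self.regions[self.frames.index(frame)]


def _mask_gap_px(a: CellRegion, b: CellRegion) -> float:
    dt = distance_transform_edt(~a.full_mask())
    rr, cc = np.nonzero(b.full_mask())
    return float(dt[rr, cc].min()) - 1.0


def _align_axes(prev: CellRegion, cur: CellRegion) -> None:
    if float(prev.axis @ cur.axis) < 0:
        cur.axis = -cur.axis


def track_and_genealogy(
    frames: list[list[CellRegion]],
    *,
    min_gap_px: float = 2.0,
    confirm_frames: int = 2,
) -> list[TrackedCell]:
    """Link segmented frames into lineages by maximal mask overlap.

    A one-to-two overlap event is a provisional division; it is accepted once
    the two daughters remain distinct regions separated by at least
    ``min_gap_px`` for ``confirm_frames`` consecutive frames, at which point
    the daughters' mutually facing ends are recorded as their new poles.
    Unconfirmable splits keep the larger fragment on the mother's track and
    flag the other fragment.  Assignment ties are broken by centroid distance.
    """
    if len(frames) < 2:
        raise ValueError("tracking needs at least 2 frames")
    for fi, regs in enumerate(frames):
        for k, r in enumerate(regs):
            r.frame = fi
            r.label = k + 1       # unique within the frame


    # parent of each region: previous-frame region with maximal overlap
    parent: dict[tuple[int, int], CellRegion | None] = {}
    children: dict[tuple[int, int], list[CellRegion]] = {}
    for fi in range(1, len(frames)):
        for r in frames[fi]:
            best, best_ov, best_d = None, 0, math.inf
            for p in frames[fi - 1]:
                ov = r.overlap(p)
                if ov == 0:
                    continue
                d = float(np.linalg.norm(r.centroid - p.centroid))
                if ov > best_ov or (ov == best_ov and d < best_d):
                    best, best_ov, best_d = p, ov, d
            parent[(fi, r.label)] = best
            if best is not None:
                children.setdefault((fi - 1, best.label), []).append(r)

    def _chain(region: CellRegion, n: int) -> list[CellRegion | None]:
        """Follow single-child links forward for n frames."""
        out: list[CellRegion | None] = [region]
        cur = region
        for _ in range(n):
            nxt = children.get((cur.frame, cur.label), [])
            cur = nxt[0] if len(nxt) == 1 else None
            out.append(cur)
            if cur is None:
                break
        return out

    tracks: list[TrackedCell] = []
    owner: dict[tuple[int, int], TrackedCell] = {}

    def _new_track(region: CellRegion, mother: int | None) -> TrackedCell:
        t = TrackedCell(tid=len(tracks), mother=mother)
        tracks.append(t)
        _extend(t, region)
        return t

    def _extend(t: TrackedCell, region: CellRegion) -> None:
        if t.regions:
            _align_axes(t.regions[-1], region)
        t.frames.append(region.frame)
        t.regions.append(region)
        owner[(region.frame, region.label)] = t

    for r in frames[0]:
        _new_track(r, None)

    for fi in range(1, len(frames)):
        for r in frames[fi]:
            if (fi, r.label) in owner:
                continue
            p = parent[(fi, r.label)]
            if p is None:
                _new_track(r, None)           # entered the field
                continue
            sibs = children[(p.frame, p.label)]
            mother_track = owner.get((p.frame, p.label))
            if mother_track is None:
                _new_track(r, None)
                continue
            if len(sibs) == 1:
                _extend(mother_track, r)
                continue
            # provisional division: keep the two largest-overlap children
            sibs = sorted(sibs, key=lambda s: s.overlap(p), reverse=True)[:2]
            a, b = sibs
            confirmed = True
            chain_a, chain_b = _chain(a, confirm_frames - 1), _chain(b, confirm_frames - 1)
            for ra, rb in zip(chain_a, chain_b):
                if ra is None or rb is None or ra.label == rb.label:
                    confirmed = False
                    break
                if _mask_gap_px(ra, rb) < min_gap_px:
                    confirmed = False
                    break
            if confirmed:
                ta = _new_track(a, mother_track.tid)
                tb = _new_track(b, mother_track.tid)
                mother_track.daughters = (ta.tid, tb.tid)
                mother_track.division_frame = fi
                for d, sib in ((ta, b), (tb, a)):
                    reg = d.regions[0]
                    proj_ends = _axis_ends(reg)
                    d_new = min(proj_ends, key=lambda e: np.linalg.norm(e[1] - sib.centroid))
                    d.new_pole_at_max = d_new[0] == "max"
            else:
                mother_track.flags.append(f"unconfirmed split at frame {fi}")
                _extend(mother_track, a)
                frag = _new_track(b, None)
                frag.flags.append("fragment of unconfirmed split")
        # any mother whose children were all consumed ends naturally

    # keep daughters' axis orientation consistent so polarity never flips
    return tracks


def _axis_ends(region: CellRegion) -> list[tuple[str, np.ndarray]]:
    coords = region.coords().astype(float)
    proj = (coords - region.centroid) @ region.axis
    return [("min", region.centroid + region.axis * proj.min()),
            ("max", region.centroid + region.axis * proj.max())]
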