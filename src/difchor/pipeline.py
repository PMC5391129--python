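"""End-to-end analysis: movie -> lineages -> choreography and focus statistics.

This is the library face of the command-line interface: it chains shape
reconstruction, segmentation, tracking, focus detection, septation detection,
kymograph/consensus construction and the aligned statistics, and returns tidy
tables with the same layout as the simulator's ground-truth tables (so any
statistic can be computed through either route and compared).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import choreography as chor
from . import foci_stats as fstats
from .imaging import (CellRegion, PoleFrame, ShapeImage, TrackedCell,
                      reconstruct_shape_image, segment_cells, subpixel_poles,
                      track_and_genealogy)
from .render import Movie

__all__ = ["AnalyzeParams", "MovieAnalysis", "analyze_movie", "analyze_snapshot",
           "match_tracks", "link_accuracy"]


@dataclass(frozen=True)
class AnalyzeParams:
    """Tunable knobs of the analysis pipeline."""

    psf_sigma_px: float = 1.5
    n_bins: int = 51
    grid: tuple[int, int] = (101, 101)
    k_septation: float = 3.0
    k_foci: float = 5.0
    min_gap_px: float = 2.0
    seg_threshold: float | None = None
    min_area_um2: float = 0.8
    projection: str = "std"


@dataclass
class MovieAnalysis:
    """All products of one movie analysis."""

    cell_frames: pd.DataFrame
    foci: pd.DataFrame
    tracks: list[TrackedCell]
    complete_tids: list[int]
    septation: dict[int, int]                 # tid -> global frame of first detection
    kymographs: dict[str, list[chor.Kymograph]]
    consensus: dict[str, chor.ConsensusImage]
    aligned: fstats.AlignedSeries | None
    shape_images: list[ShapeImage] = field(repr=False, default_factory=list)


def _oriented(track: TrackedCell) -> bool:
    """True when the per-frame profiles already run old pole -> new pole."""
    return bool(track.new_pole_at_max)


def analyze_movie(movie: Movie, params: AnalyzeParams = AnalyzeParams()) -> MovieAnalysis:
    """Run the full time-lapse pipeline on a rendered or recorded movie.

    Only cells observed from birth to their own confirmed division (complete
    cell cycles) enter the choreography statistics, and their profiles are
    oriented using the polarity fixed at their birth division.
    """
    shapes = [reconstruct_shape_image(movie.brightfield[t], movie.pixel_size,
                                      method=params.projection)
              for t in range(movie.n_frames)]
    frames = [segment_cells(s, threshold=params.seg_threshold,
                            min_area_um2=params.min_area_um2) for s in shapes]
    tracks = track_and_genealogy(frames, min_gap_px=params.min_gap_px)

    complete = [t for t in tracks if t.complete and t.new_pole_at_max is not None]
    cf_rows, foci_rows = [], []
    septation: dict[int, int] = {}
    kymos: dict[str, list[chor.Kymograph]] = {"fluor": [], "shape": []}

    grid_x = np.linspace(0.0, 1.0, params.n_bins)
    for tr in complete:
        prof_fluor, prof_shape, prof_sept = [], [], []
        poles_by_frame: dict[int, PoleFrame] = {}
        for fi, reg in zip(tr.frames, tr.regions):
            poles = subpixel_poles(shapes[fi].data, reg)
            poles_by_frame[fi] = poles
            # adaptive (~2 px) slices for detection; fixed grid for kymographs
            pf = chor.long_axis_profile(movie.fluorescence[fi], reg,
                                        n_bins=None, poles=poles)
            ps = chor.long_axis_profile(shapes[fi].data, reg,
                                        n_bins=None, poles=poles)
            prof_sept.append(ps.values)
            src_f = np.linspace(0.0, 1.0, len(pf.values))
            src_s = np.linspace(0.0, 1.0, len(ps.values))
            prof_fluor.append(np.interp(grid_x, src_f, pf.values))
            prof_shape.append(np.interp(grid_x, src_s, ps.values))

        call = chor.detect_septation(prof_sept, k=params.k_septation) \
            if len(prof_sept) >= 3 else None
        sept_global = tr.frames[call.frame] if call is not None else None
        if sept_global is not None:
            septation[tr.tid] = sept_global

        flip = not _oriented(tr)
        kymos["fluor"].append(chor.kymograph_from_profiles(
            prof_fluor, grid=params.grid, channel="fluor", flip=flip))
        kymos["shape"].append(chor.kymograph_from_profiles(
            prof_shape, grid=params.grid, channel="shape", flip=flip))

        for fi, reg in zip(tr.frames, tr.regions):
            poles = poles_by_frame[fi]
            found = fstats.detect_foci(movie.fluorescence[fi], reg,
                                       params.psf_sigma_px, poles=poles,
                                       k=params.k_foci, cell=tr.tid)
            for f in found:
                x = f.x if _oriented(tr) else 1.0 - f.x
                foci_rows.append(dict(cell=tr.tid, frame=fi, x=x,
                                      d=abs(x - 0.5), intensity=f.intensity))
            cf_rows.append(dict(cell=tr.tid, frame=fi,
                                time=float(movie.times[fi]),
                                length=poles.length_px * movie.pixel_size,
                                n_foci=len(found),
                                sept_frame=sept_global))

    cell_frames = pd.DataFrame(cf_rows, columns=["cell", "frame", "time",
                                                 "length", "n_foci", "sept_frame"])
    foci = pd.DataFrame(foci_rows, columns=["cell", "frame", "x", "d", "intensity"])
    consensus = {ch: chor.consensus_image(ks) for ch, ks in kymos.items() if ks}
    aligned = None
    if not cell_frames.empty and cell_frames["sept_frame"].notna().any():
        aligned = fstats.align_to_septation(cell_frames, foci, movie.frame_interval)
    return MovieAnalysis(cell_frames=cell_frames, foci=foci, tracks=tracks,
                         complete_tids=[t.tid for t in complete],
                         septation=septation, kymographs=kymos,
                         consensus=consensus, aligned=aligned,
                         shape_images=shapes)


def analyze_snapshot(movie: Movie, params: AnalyzeParams = AnalyzeParams()
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyse a single-frame image set: per-cell table + per-focus table.

    Orientation is the segmenter's canonical axis direction (pole identity is
    unknowable in snapshots); positions are therefore only meaningful up to a
    mirror flip, exactly as in arbitrary-orientation snapshot analyses.
    """
    shape = reconstruct_shape_image(movie.brightfield[0], movie.pixel_size,
                                    method=params.projection)
    regions = segment_cells(shape, threshold=params.seg_threshold,
                            min_area_um2=params.min_area_um2)
    cells, foci = [], []
    for i, reg in enumerate(regions):
        poles = subpixel_poles(shape.data, reg)
        prof = chor.long_axis_profile(shape.data, reg, n_bins=None, poles=poles)
        constricting = chor.classify_constriction(prof, k=params.k_septation)[0]
        found = fstats.detect_foci(movie.fluorescence[0], reg,
                                   params.psf_sigma_px, poles=poles,
                                   k=params.k_foci, cell=i)
        cells.append(dict(cell=i, length=poles.length_px * movie.pixel_size,
                          constricting=constricting, n_foci=len(found),
                          centroid_row=reg.centroid[0], centroid_col=reg.centroid[1]))
        for f in found:
            foci.append(dict(cell=i, x=f.x, d=f.d, intensity=f.intensity))
    return (pd.DataFrame(cells, columns=["cell", "length", "constricting", "n_foci",
                                         "centroid_row", "centroid_col"]),
            pd.DataFrame(foci, columns=["cell", "x", "d", "intensity"]))


# ---------------------------------------------------------------------------
# truth matching (validation utilities)

def match_tracks(analysis: MovieAnalysis, movie: Movie,
                 tids: list[int] | None = None) -> dict[int, str]:
    """Map track ids to ground-truth cell ids via the render layout.

    A track matches the truth cell whose rendered centre lies closest to the
    track's centroid in the track's first frame (and within half a lane).
    """
    if movie.layout is None or movie.layout.empty:
        raise ValueError("movie carries no ground-truth layout")
    lay = movie.layout
    out: dict[int, str] = {}
    for tr in analysis.tracks:
        if tids is not None and tr.tid not in tids:
            continue
        if not tr.frames:
            continue
        fi, reg = tr.frames[0], tr.regions[0]
        cand = lay[lay["frame"] == fi]
        if cand.empty:
            continue
        cx = cand["x0"] + cand["length_px"] / 2.0
        dist = np.hypot(cx - reg.centroid[1], cand["y"] - reg.centroid[0])
        j = int(np.argmin(dist.to_numpy()))
        if dist.to_numpy()[j] < 8.0:
            out[tr.tid] = cand.iloc[j]["cell"]
    return out


def link_accuracy(analysis: MovieAnalysis, movie: Movie) -> float:
    """Fraction of tracked mother-daughter links that match the ground truth."""
    mapping = match_tracks(analysis, movie)
    truth = movie.truth
    if truth is None:
        raise ValueError("movie carries no ground truth")
    total = correct = 0
    for tr in analysis.tracks:
        if tr.mother is None or tr.tid not in mapping:
            continue
        mother_tr = analysis.tracks[tr.mother]
        total += 1
        if mother_tr.tid in mapping:
            truth_cell = truth.cells.get(mapping[tr.tid])
            if truth_cell is not None and truth_cell.parent == mapping[mother_tr.tid]:
                correct += 1
    if total == 0:
        raise ValueError("no mother-daughter links to score")
    return correct / total
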