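"""Render simulated lineages into fluorescence + bright-field movies.

Cells are drawn as capsules (rectangles with hemispherical caps) lying
horizontally in per-founder lanes; at division the two daughters replace the
mother side by side with a small visible gap.  The fluorescence channel is a
sum of isotropic Gaussian spots at the true focus positions over a constant
background; the bright-field channel is a defocus stack in which the cell-body
contrast flips sign through focus, so that a standard-deviation projection
across the stack reconstructs the cell shape.  From the constriction onset
onwards a transverse dark line of growing depth is drawn at mid-cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.ndimage import gaussian_filter

from .config import SimulationConfig
from .simgen import GroundTruth, SimCell, _stream

__all__ = ["Movie", "render_movie", "render_snapshot", "write_movie", "read_movie"]

GAP_PX = 6          # visible gap between sibling cells after scission
LANE_MARGIN = 12    # px of clear background at each lane end
EDGE_SOFT = 1.0     # px, softness of the capsule edge


@dataclass
class Movie:
    """Rendered movie plus the layout table linking pixels to ground truth."""

    fluorescence: np.ndarray            # (T, H, W) float32
    brightfield: np.ndarray             # (T, P, H, W) float32
    times: np.ndarray                   # min
    pixel_size: float                   # um/px
    frame_interval: float               # min
    layout: pd.DataFrame | None = None  # cell placements per frame
    truth: GroundTruth | None = None
    config: SimulationConfig | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[0]


def _lane_order(truth: GroundTruth, cell: SimCell, t: float) -> list[SimCell]:
    """Live descendants of *cell* at time t in left-to-right lane order."""
    if truth.alive(cell, t) or cell.daughters is None:
        return [cell] if truth.alive(cell, t) else []
    d_old, d_new = (truth.cells[d] for d in cell.daughters)
    left, right = (d_old, d_new) if cell.orient > 0 else (d_new, d_old)
    return _lane_order(truth, left, t) + _lane_order(truth, right, t)


def _compute_layout(truth: GroundTruth, times: np.ndarray) -> tuple[pd.DataFrame, int, int]:
    cfg = truth.config
    px = cfg.pixel_size
    lane_h = int(math.ceil(cfg.cell_width / px)) + 9
    rows = []
    max_extent = 1.0
    for lane, root_id in enumerate(truth.roots):
        root = truth.cells[root_id]
        for fi, t in enumerate(times):
            cells = _lane_order(truth, root, t)
            if not cells:
                continue
            lengths = [truth.length(c, t) / px for c in cells]
            total = sum(lengths) + GAP_PX * (len(cells) - 1)
            max_extent = max(max_extent, total)
            rows.append((lane, fi, t, cells, lengths, total))
    W = int(math.ceil(max_extent)) + 2 * LANE_MARGIN
    H = lane_h * max(1, len(truth.roots))
    out = []
    for lane, fi, t, cells, lengths, total in rows:
        x = (W - total) / 2.0
        yc = lane * lane_h + lane_h / 2.0 - 0.5
        for c, L in zip(cells, lengths):
            out.append(dict(cell=c.id, frame=fi, time=t, lane=lane,
                            x0=x, length_px=L, y=yc, orient=c.orient))
            x += L + GAP_PX
    layout = pd.DataFrame(out, columns=["cell", "frame", "time", "lane",
                                        "x0", "length_px", "y", "orient"])
    return layout, H, W


def _draw_body(canvas: np.ndarray, x0: float, L: float, yc: float,
               radius: float, septum: tuple[float, float] | None) -> None:
    """Additively draw one soft-edged capsule (optionally constricted)."""
    h, w = canvas.shape
    xlo = max(0, int(math.floor(x0 - 2)))
    xhi = min(w, int(math.ceil(x0 + L + 3)))
    ylo = max(0, int(math.floor(yc - radius - 2)))
    yhi = min(h, int(math.ceil(yc + radius + 3)))
    if xhi <= xlo or yhi <= ylo:
        return
    xs = np.arange(xlo, xhi)[None, :]
    ys = np.arange(ylo, yhi)[:, None]
    cx = x0 + L / 2.0
    half = max(L / 2.0 - radius, 0.0)
    dx = np.maximum(np.abs(xs - cx) - half, 0.0)
    d = np.hypot(dx, ys - yc)
    body = np.clip((radius - d) / EDGE_SOFT + 0.5, 0.0, 1.0)
    if septum is not None:
        depth, sigma = septum
        body *= 1.0 - depth * np.exp(-0.5 * ((xs - cx) / sigma) ** 2)
    canvas[ylo:yhi, xlo:xhi] += body


def _septum_depth(cfg: SimulationConfig, t: float, t_con_abs: float) -> float:
    ramp = (t - t_con_abs) / max(cfg.septum_ramp_time, 1e-9)
    return min(cfg.septum_depth_max,
               cfg.septum_depth0 + (cfg.septum_depth_max - cfg.septum_depth0)
               * max(0.0, ramp))


def _add_spot(img: np.ndarray, x: float, y: float, amp: float, sigma: float) -> None:
    h, w = img.shape
    r = int(math.ceil(5 * sigma))
    xlo, xhi = max(0, int(x) - r), min(w, int(x) + r + 1)
    ylo, yhi = max(0, int(y) - r), min(h, int(y) + r + 1)
    if xhi <= xlo or yhi <= ylo:
        return
    xs = np.arange(xlo, xhi)[None, :]
    ys = np.arange(ylo, yhi)[:, None]
    img[ylo:yhi, xlo:xhi] += amp * np.exp(-((xs - x) ** 2 + (ys - y) ** 2)
                                          / (2.0 * sigma ** 2))


def render_movie(truth: GroundTruth, times: np.ndarray | None = None) -> Movie:
    """Render every frame of a simulated population.

    Ground-truth focus positions (including jitter) are evaluated at the same
    frame indices used by :meth:`GroundTruth.foci`, so the rendered spots and
    the oracle tables agree exactly.
    """
    cfg = truth.config
    if times is None:
        times = truth.frame_times()
    times = np.asarray(times, dtype=float)
    layout, H, W = _compute_layout(truth, times)
    if layout.empty:
        H, W = 24, 64
    T, P = len(times), cfg.n_stack_planes
    px = cfg.pixel_size
    radius = cfg.cell_width / (2.0 * px)
    psf_px = cfg.psf_sigma_px()
    ztilde = np.linspace(-1.0, 1.0, P)

    fluor = np.empty((T, H, W), dtype=np.float32)
    bf = np.empty((T, P, H, W), dtype=np.float32)
    warnings_: list[str] = []
    foci_rows = []

    by_frame = {fi: g for fi, g in layout.groupby("frame")} if not layout.empty else {}
    for fi, t in enumerate(times):
        body = np.zeros((H, W), dtype=float)
        spots = np.zeros((H, W), dtype=float)
        for row in by_frame.get(fi, pd.DataFrame()).itertuples():
            cell = truth.cells[row.cell]
            sept = None
            if t >= cell.t_con_abs - 1e-9:
                sept = (_septum_depth(cfg, t, cell.t_con_abs), cfg.septum_line_sigma)
            _draw_body(body, row.x0, row.length_px, row.y, radius, sept)
            for u in truth.foci(cell, t, frame=fi):
                lx = row.x0 + (u if row.orient > 0 else 1.0 - u) * row.length_px
                _add_spot(spots, lx, row.y, cfg.spot_amplitude, psf_px)
                foci_rows.append(dict(cell=cell.id, frame=fi, x_px=lx, y_px=row.y, u=u))
        if body.max() > 1.0 + 1e-6:
            warnings_.append(f"frame {fi}: overlapping cells in the field")
            body = np.clip(body, 0.0, 1.0)
        f_img = cfg.background + spots
        if cfg.noise_sd > 0:
            rng = _stream(truth.seed, "noise", fi, "fluor")
            f_img = f_img + rng.normal(0.0, cfg.noise_sd, size=f_img.shape)
        fluor[fi] = f_img
        for p, z in enumerate(ztilde):
            sigma = 0.6 + 1.6 * abs(z)
            plane = cfg.background + cfg.bf_contrast * z * gaussian_filter(body, sigma)
            if cfg.noise_sd > 0:
                rng = _stream(truth.seed, "noise", fi, "bf", p)
                plane = plane + rng.normal(0.0, cfg.noise_sd, size=plane.shape)
            bf[fi, p] = plane

    foci_px = pd.DataFrame(foci_rows, columns=["cell", "frame", "x_px", "y_px", "u"])
    layout = layout.merge(foci_px.groupby(["cell", "frame"]).size()
                          .rename("n_foci").reset_index(),
                          on=["cell", "frame"], how="left") if not layout.empty else layout
    return Movie(fluorescence=fluor, brightfield=bf, times=times,
                 pixel_size=px, frame_interval=cfg.frame_interval,
                 layout=layout, truth=truth, config=cfg, warnings=warnings_)


def render_snapshot(truth: GroundTruth, time: float) -> Movie:
    """Single-frame render of the population at *time* (nearest frame time)."""
    times = truth.frame_times()
    t = times[int(np.argmin(np.abs(times - time)))]
    return render_movie(truth, times=np.array([t]))


# ---------------------------------------------------------------------------
# disk format: multi-page TIFF + sidecar CSV/YAML

def write_movie(movie: Movie, out_dir) -> dict[str, Path]:
    """Write movie.tif (frame-major pages: fluorescence then BF planes),
    ground-truth sidecar CSVs and a YAML echo of the configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    T, P = movie.n_frames, movie.brightfield.shape[1]
    pages = np.concatenate([movie.fluorescence[:, None], movie.brightfield], axis=1)
    pages = pages.reshape(T * (P + 1), *movie.fluorescence.shape[1:]).astype(np.float32)
    meta = dict(n_frames=T, n_planes=P,
                pixel_size=movie.pixel_size, frame_interval=movie.frame_interval,
                times=[float(t) for t in movie.times])
    paths = {"movie": out / "movie.tif"}
    tifffile.imwrite(paths["movie"], pages, description=json.dumps(meta))
    if movie.layout is not None and movie.truth is not None:
        truth = movie.truth
        lay = movie.layout.copy()
        lay["length_um"] = lay["length_px"] * movie.pixel_size
        lay["septation"] = [
            t >= truth.cells[c].t_con_abs - 1e-9
            for c, t in zip(lay["cell"], lay["time"])
        ]
        paths["truth"] = out / "truth_cells.csv"
        lay.to_csv(paths["truth"], index=False)
        foci_rows = [
            dict(cell=c.id, frame=int(fi), time=truth.frame_times()[fi],
                 focus=j, rel_pos=x)
            for c in truth.cells.values()
            for fi in truth.frames_of(c) if fi < len(movie.times)
            for j, x in enumerate(truth.foci(c, truth.frame_times()[fi],
                                             frame=int(fi)))
        ]
        paths["truth_foci"] = out / "truth_foci.csv"
        pd.DataFrame(foci_rows, columns=["cell", "frame", "time", "focus",
                                         "rel_pos"]).to_csv(paths["truth_foci"],
                                                            index=False)
    elif movie.layout is not None:
        paths["truth"] = out / "truth_cells.csv"
        movie.layout.to_csv(paths["truth"], index=False)
    if movie.config is not None:
        paths["config"] = out / "config.yaml"
        with open(paths["config"], "w") as fh:
            yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in vars(movie.config).items()}, fh)
    return paths


def read_movie(path) -> Movie:
    """Read a movie written by :func:`write_movie` (truth not reattached)."""
    path = Path(path)
    tif = path / "movie.tif" if path.is_dir() else path
    with tifffile.TiffFile(tif) as fh:
        pages = fh.asarray()
        meta = json.loads(fh.pages[0].description)
    T, P = meta["n_frames"], meta["n_planes"]
    pages = pages.reshape(T, P + 1, *pages.shape[1:])
    return Movie(fluorescence=pages[:, 0], brightfield=pages[:, 1:],
                 times=np.asarray(meta["times"]),
                 pixel_size=meta["pixel_size"],
                 frame_interval=meta["frame_interval"])
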