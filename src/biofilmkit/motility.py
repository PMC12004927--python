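"""Cell detection, track linking and motility statistics.

Videos of swimming cells are reduced to tracks in the classic
detect-then-link way: a band-pass filter (Gaussian smoothing at the spot
scale minus a boxcar background estimate) isolates spot-like features,
local maxima are refined to sub-pixel centres by intensity-weighted
centroids, and detections are linked frame-to-frame by optimal bipartite
assignment (minimum total displacement within a search radius, with a
memory parameter bridging short gaps).

From the tracks come the study's motility statistics: per-step speeds
pooled over every step of every track (so "maximum velocity" is the single
largest step), a motile/immotile classification (mean speed AND net
displacement must both exceed thresholds — the criterion is this package's
definition, both thresholds are configuration keys), motile fractions per
spatial distance bin, vertical distributions (median and interquartile
range), per-frame cell counts for growth rates, and gridded velocity
fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from . import segment as _segment

__all__ = [
    "detect_particles",
    "link_detections",
    "step_table",
    "track_kinematics",
    "population_speed_stats",
    "classify_motile",
    "motile_fraction_binned",
    "VerticalDistribution",
    "vertical_distribution",
    "count_cells_series",
    "velocity_field",
    "assign_z_by_focus",
]


# --------------------------------------------------------------------------
# Detection
# --------------------------------------------------------------------------

def detect_particles(
    pixels: np.ndarray,
    spot_diameter_px: int = 7,
    min_mass: float = 0.0,
    peak_threshold: float = 0.05,
    invert: bool = False,
) -> pd.DataFrame:
    """Detect bright spot-like cells in one frame.

    Band-pass = Gaussian smoothing (σ = diameter/4) minus a boxcar
    background over ~2 diameters; local maxima of the band-passed image
    above ``peak_threshold`` are refined to sub-pixel positions by an
    intensity-weighted centroid over the spot window.  ``mass`` is the
    integrated band-passed intensity in that window; detections below
    ``min_mass`` are discarded.  Set ``invert`` for dark-on-bright contrast.

    Returns a DataFrame (x_px, y_px, mass); empty when nothing is found.
    """
    if spot_diameter_px < 3 or spot_diameter_px % 2 == 0:
        raise ValueError("spot_diameter_px must be odd and >= 3")
    if hasattr(pixels, "pixels"):
        pixels = pixels.pixels
    img = np.asarray(pixels, float)
    if invert:
        img = 1.0 - img
    sigma = spot_diameter_px / 4.0
    smoothed = ndimage.gaussian_filter(img, sigma)
    background = ndimage.uniform_filter(img, 2 * spot_diameter_px + 1)
    bp = np.clip(smoothed - background, 0.0, None)

    footprint = np.ones((spot_diameter_px, spot_diameter_px), bool)
    local_max = (ndimage.maximum_filter(bp, footprint=footprint) == bp)
    peaks = np.argwhere(local_max & (bp > peak_threshold))

    half = spot_diameter_px // 2
    h, w = bp.shape
    rows = []
    for py, px in peaks:
        y0, y1 = max(0, py - half), min(h, py + half + 1)
        x0, x1 = max(0, px - half), min(w, px + half + 1)
        window = bp[y0:y1, x0:x1]
        mass = float(window.sum())
        if mass < min_mass or mass == 0.0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        rows.append({
            "x_px": float((window * xx).sum() / mass),
            "y_px": float((window * yy).sum() / mass),
            "mass": mass,
        })
    return pd.DataFrame(rows, columns=["x_px", "y_px", "mass"])


def detect_video(
    video, spot_diameter_px: int = 7, min_mass: float = 0.0,
    peak_threshold: float = 0.05, invert: bool = False,
) -> pd.DataFrame:
    """Run :func:`detect_particles` over every frame of a video.

    Returns one DataFrame with a ``frame`` column prepended.
    """
    frames = video.frames if hasattr(video, "frames") else video
    parts = []
    for t, fr in enumerate(frames):
        det = detect_particles(fr, spot_diameter_px, min_mass,
                               peak_threshold, invert)
        det.insert(0, "frame", t)
        parts.append(det)
    if not parts:
        return pd.DataFrame(columns=["frame", "x_px", "y_px", "mass"])
    return pd.concat(parts, ignore_index=True)


# --------------------------------------------------------------------------
# Linking
# --------------------------------------------------------------------------

_UNMATCHED = 1e12


def link_detections(
    detections: pd.DataFrame,
    search_radius_px: float,
    memory_frames: int = 0,
) -> pd.DataFrame:
    """Link per-frame detections into tracks.

    Per frame pair the assignment minimising total displacement among pairs
    within the search radius is found (optimal bipartite matching);
    unmatched detections seed new tracks; a track missing from up to
    ``memory_frames`` consecutive frames may still be extended (its last
    seen position is used).  Returns the detections with a ``track_id``
    column added, sorted by (track_id, frame).
    """
    if search_radius_px <= 0:
        raise ValueError("search_radius_px must be > 0")
    if memory_frames < 0:
        raise ValueError("memory_frames must be >= 0")
    if detections.empty:
        out = detections.copy()
        out["track_id"] = pd.Series(dtype=int)
        return out

    det = detections.sort_values(["frame"], kind="stable").reset_index(drop=True)
    det["track_id"] = -1
    next_id = 0
    # active: track_id -> (last_frame, x, y)
    active: dict[int, tuple[int, float, float]] = {}

    for frame, group in det.groupby("frame", sort=True):
        idx = group.index.to_numpy()
        xy = group[["x_px", "y_px"]].to_numpy()
        # tracks still within memory, deterministically ordered by id
        cand = sorted(
            tid for tid, (lf, _, _) in active.items()
            if frame - lf <= memory_frames + 1
        )
        assigned = np.full(len(idx), -1)
        if cand and len(idx):
            last = np.array([[active[t][1], active[t][2]] for t in cand])
            d = np.hypot(last[:, 0, None] - xy[None, :, 0],
                         last[:, 1, None] - xy[None, :, 1])
            cost = np.where(d <= search_radius_px, d, _UNMATCHED)
            # pad to square so every row/col may stay unmatched
            n = len(cand) + len(idx)
            big = np.full((n, n), _UNMATCHED / 2)
            big[: len(cand), : len(idx)] = cost
            r, c = linear_sum_assignment(big)
            for ri, ci in zip(r, c):
                if ri < len(cand) and ci < len(idx) and cost[ri, ci] < _UNMATCHED:
                    assigned[ci] = cand[ri]
        for k, di in enumerate(idx):
            tid = assigned[k]
            if tid < 0:
                tid = next_id
                next_id += 1
            det.loc[di, "track_id"] = tid
            active[tid] = (int(frame), float(det.loc[di, "x_px"]),
                           float(det.loc[di, "y_px"]))
        # retire tracks that fell out of memory
        active = {t: v for t, v in active.items()
                  if frame - v[0] <= memory_frames}
    return det.sort_values(["track_id", "frame"]).reset_index(drop=True)


# --------------------------------------------------------------------------
# Kinematics
# --------------------------------------------------------------------------

def step_table(tracks: pd.DataFrame, fps: float, pixel_size_um: float) -> pd.DataFrame:
    """Per-step velocities for every track.

    Step speed = Euclidean displacement × pixel_size × fps / frame gap.
    Columns: track_id, frame (step start), gap, speed_um_s, vx_um_s,
    vy_um_s, mid_x_px, mid_y_px.
    """
    rows = []
    for tid, g in tracks.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        if len(g) < 2:
            continue
        f = g["frame"].to_numpy()
        x = g["x_px"].to_numpy()
        y = g["y_px"].to_numpy()
        gap = np.diff(f)
        dx, dy = np.diff(x), np.diff(y)
        scale = pixel_size_um * fps / gap
        rows.append(pd.DataFrame({
            "track_id": tid,
            "frame": f[:-1],
            "gap": gap,
            "speed_um_s": np.hypot(dx, dy) * scale,
            "vx_um_s": dx * scale,
            "vy_um_s": dy * scale,
            "mid_x_px": (x[:-1] + x[1:]) / 2,
            "mid_y_px": (y[:-1] + y[1:]) / 2,
        }))
    cols = ["track_id", "frame", "gap", "speed_um_s", "vx_um_s", "vy_um_s",
            "mid_x_px", "mid_y_px"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.concat(rows, ignore_index=True)


def track_kinematics(tracks: pd.DataFrame, fps: float,
                     pixel_size_um: float,
                     drop_singletons: bool = False) -> pd.DataFrame:
    """Per-track summary: mean/max step speed, net displacement, mean position.

    A single-point track has no kinematics: by default it raises; with
    ``drop_singletons`` it is silently excluded (population pipelines, where
    unlinked spurious detections are expected).  Columns: track_id,
    n_points, mean_speed_um_s, max_speed_um_s, net_disp_um, mean_x_px,
    mean_y_px.
    """
    steps = step_table(tracks, fps, pixel_size_um)
    rows = []
    for tid, g in tracks.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        if len(g) < 2:
            if drop_singletons:
                continue
            raise ValueError(f"track {tid} has a single point; no kinematics")
        s = steps[steps["track_id"] == tid]["speed_um_s"]
        net = np.hypot(g["x_px"].iloc[-1] - g["x_px"].iloc[0],
                       g["y_px"].iloc[-1] - g["y_px"].iloc[0]) * pixel_size_um
        rows.append({
            "track_id": tid,
            "n_points": len(g),
            "mean_speed_um_s": float(s.mean()),
            "max_speed_um_s": float(s.max()),
            "net_disp_um": float(net),
            "mean_x_px": float(g["x_px"].mean()),
            "mean_y_px": float(g["y_px"].mean()),
        })
    return pd.DataFrame(rows)


def population_speed_stats(steps: pd.DataFrame) -> tuple[float, float, float]:
    """(mean, max, SD) of speed pooled over every step of every track.

    Statistics are per step, not per track, so the maximum is the single
    fastest step observed anywhere.  SD is the population SD.
    """
    s = steps["speed_um_s"].to_numpy()
    if s.size == 0:
        raise ValueError("no steps to pool")
    return float(s.mean()), float(s.max()), float(s.std(ddof=0))


def classify_motile(
    kinematics: pd.DataFrame,
    speed_threshold_um_s: float = 1.0,
    net_disp_threshold_um: float = 2.0,
) -> pd.DataFrame:
    """Flag tracks as motile: mean speed AND net displacement above thresholds.

    The double criterion rejects stationary cells whose localisation jitter
    inflates apparent speed but produces negligible net displacement.
    """
    out = kinematics.copy()
    out["motile"] = (
        (out["mean_speed_um_s"] >= speed_threshold_um_s)
        & (out["net_disp_um"] >= net_disp_threshold_um)
    )
    return out


def motile_fraction_binned(
    kinematics: pd.DataFrame,
    bin_edges_mm: np.ndarray,
    pixel_size_um: float,
    axis: str = "x",
    weight_by_length: bool = False,
) -> pd.DataFrame:
    """Motile-track fraction per spatial distance bin.

    Tracks are assigned to one bin by their mean position along ``axis``;
    empty bins report NaN (undefined, not zero); tracks outside all bins are
    counted in an overflow row (bin −1).  With ``weight_by_length`` each
    track contributes its point count instead of 1, which cancels the bias
    introduced when broken tracks make one cell count several times.
    """
    edges_px = np.asarray(bin_edges_mm, float) * 1000.0 / pixel_size_um
    pos = kinematics[f"mean_{axis}_px"].to_numpy()
    which = np.searchsorted(edges_px, pos, side="right") - 1
    which[(pos < edges_px[0]) | (pos >= edges_px[-1])] = -1
    motile = kinematics["motile"].to_numpy()
    weights = (kinematics["n_points"].to_numpy().astype(float)
               if weight_by_length else np.ones(len(kinematics)))
    rows = []
    for b in range(len(edges_px) - 1):
        sel = which == b
        n = int(sel.sum())
        wsum = weights[sel].sum()
        rows.append({
            "bin": b,
            "x0_mm": bin_edges_mm[b],
            "x1_mm": bin_edges_mm[b + 1],
            "n_tracks": n,
            "n_motile": int(motile[sel].sum()),
            "motile_fraction": (float((weights[sel] * motile[sel]).sum() / wsum)
                                if n else np.nan),
        })
    n_over = int((which == -1).sum())
    if n_over:
        rows.append({
            "bin": -1, "x0_mm": np.nan, "x1_mm": np.nan,
            "n_tracks": n_over, "n_motile": int(motile[which == -1].sum()),
            "motile_fraction": float(motile[which == -1].mean()),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Distributions, counts, fields
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VerticalDistribution:
    """Median and interquartile range of cell heights above the dish bottom."""

    median_um: float
    q25_um: float
    q75_um: float
    n: int

    @property
    def iqr_um(self) -> float:
        return self.q75_um - self.q25_um


def vertical_distribution(z_positions_um: np.ndarray) -> VerticalDistribution:
    """Median and 25/75 quantiles (linear-interpolation rule) of Z positions."""
    z = np.asarray(z_positions_um, float)
    if z.size < 4:
        raise ValueError("need at least 4 positions")
    q25, med, q75 = np.percentile(z, [25, 50, 75], method="linear")
    return VerticalDistribution(float(med), float(q25), float(q75), z.size)


def assign_z_by_focus(stack, xy_positions: np.ndarray, window_px: int = 7) -> np.ndarray:
    """Height of each cell = the Z of its sharpest slice.

    Per cell, the variance of the Laplacian inside a window around its XY
    position is evaluated on every slice; the slice maximising this focus
    score gives the cell's Z in μm above the dish bottom.
    """
    arr = stack.as_array()
    zs = stack.z_positions_um()
    half = window_px // 2
    n_z, h, w = arr.shape
    lap = np.stack([ndimage.laplace(arr[k]) for k in range(n_z)])
    out = np.empty(len(xy_positions))
    for i, (x, y) in enumerate(np.asarray(xy_positions, float)):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(0, cx - half), min(w, cx + half + 1)
        y0, y1 = max(0, cy - half), min(h, cy + half + 1)
        scores = lap[:, y0:y1, x0:x1].reshape(n_z, -1).var(axis=1)
        out[i] = zs[int(np.argmax(scores))]
    return out


def count_cells_series(
    frames,
    pixel_size_um: float | None = None,
    n_classes: int = 2,
    foreground_classes: frozenset[int] = frozenset({0}),
    cell_area_max_um2: float = 50.0,
    min_area_um2: float = 3.0,
) -> pd.DataFrame:
    """Per-frame CELL-region counts by segmentation.

    Thresholds are multi-Otsu over a histogram pooled across the whole
    series — detection parameters are fixed across frames, so counts are
    comparable over time and a frame without biofilm cannot degenerate the
    threshold placement.  The default is a 2-class split (dark features vs
    bright background); features are then told apart by area, and the count
    is the number of CELL-class regions.  Columns: frame, timestamp_s,
    n_cells, biofilm_area_um2.
    """
    arrays = [fr.pixels if hasattr(fr, "pixels") else np.asarray(fr, float)
              for fr in frames]
    hist = _segment.intensity_histogram(np.concatenate([a.ravel() for a in arrays]))
    thr = _segment.multi_otsu_thresholds(hist, n_classes=n_classes)
    rows = []
    for t, (fr, px) in enumerate(zip(frames, arrays)):
        psize = pixel_size_um or getattr(fr, "pixel_size_um", None)
        if psize is None:
            raise ValueError("pixel size unknown; pass pixel_size_um")
        mask = _segment.apply_thresholds(px, thr, foreground_classes)
        lab = _segment.label_components(mask, connectivity=8)
        table = _segment.region_properties(lab, psize)
        table = _segment.classify_regions(table, cell_area_max_um2, min_area_um2)
        rows.append({
            "frame": t,
            "timestamp_s": getattr(fr, "timestamp_s", float(t)),
            "n_cells": int((table["region_class"] == _segment.CELL).sum()),
            "biofilm_area_um2": float(
                table.loc[table["region_class"] == _segment.BIOFILM, "area_um2"].sum()
            ),
        })
    return pd.DataFrame(rows)


def velocity_field(
    steps: pd.DataFrame,
    grid_px: int,
    frame_shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gridded mean velocity vectors (μm/s).

    Each step's velocity vector is binned at its midpoint.  Returns
    ``(vx, vy, count)`` arrays of shape (ny, nx); cells with zero samples
    hold NaN velocity (explicitly empty, never zero).
    """
    if grid_px < 1:
        raise ValueError("grid_px must be >= 1")
    h, w = frame_shape
    ny = int(np.ceil(h / grid_px))
    nx = int(np.ceil(w / grid_px))
    vx_sum = np.zeros((ny, nx))
    vy_sum = np.zeros((ny, nx))
    count = np.zeros((ny, nx), int)
    gx = np.clip((steps["mid_x_px"].to_numpy() / grid_px).astype(int), 0, nx - 1)
    gy = np.clip((steps["mid_y_px"].to_numpy() / grid_px).astype(int), 0, ny - 1)
    np.add.at(vx_sum, (gy, gx), steps["vx_um_s"].to_numpy())
    np.add.at(vy_sum, (gy, gx), steps["vy_um_s"].to_numpy())
    np.add.at(count, (gy, gx), 1)
    with np.errstate(invalid="ignore"):
        vx = np.where(count > 0, vx_sum / np.maximum(count, 1), np.nan)
        vy = np.where(count > 0, vy_sum / np.maximum(count, 1), np.nan)
    return vx, vy, count
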