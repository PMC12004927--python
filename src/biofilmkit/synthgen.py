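"""Synthetic microscopy scenes with exact ground truth.

No raw imagery is deposited for the study system (sulfate-reducing bacteria
growing on H₂ or lactate in μ-dishes, μ-channels and a microfluidic pore
network), so every analysis operation in this package is exercised against
synthetic scenes whose ground truth is known exactly and whose *statistics*
are parameterised from the printed numbers: condition-dependent swimming
speed distributions, motile fractions decaying with distance from the
gas/liquid interface, planktonic growth rates, and multi-cycle biofilm
detachment schedules in a pore network.

Everything here is a statistical stand-in: no hydrodynamics, chemotaxis
mechanism, pH evolution or H₂ dissolution is simulated.  Trajectories are
persistent random walks, biofilms are grain-hugging pixel coats and
ellipsoidal blobs, gas is a non-wetting phase occupying the largest pore
bodies.  The point is that the *measurement pipeline* can be validated
against exact ground truth.

Determinism contract: every generator takes a single integer ``seed``;
rerunning with the same seed reproduces imagery and ground truth
bit-identically.  Randomness is drawn from per-object sub-streams keyed by
``(seed, object index)`` so increasing ``n_cells`` never changes earlier
cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from skimage import measure as _skmeasure

from .images import ImageFrame, ImageStack, VideoSequence
from .poremetrics import BIOFILM, GAS, GRAIN, LIQUID, PhaseMap

__all__ = [
    "Preset",
    "get_preset",
    "list_presets",
    "TrackGroundTruth",
    "generate_pore_network",
    "simulate_motility_video",
    "simulate_channel_gradient",
    "simulate_biofilm_zstack",
    "simulate_detachment_series",
    "simulate_paired_saturation",
    "simulate_growth_series",
    "DetachmentSeries",
    "ZStackGroundTruth",
]


# --------------------------------------------------------------------------
# Presets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Preset:
    """Named parameter set for a generator.

    ``provenance`` documents, per parameter, whether the value is a printed
    study statistic ("measured"), derived from printed values ("derived"), or a
    generator default chosen by this package ("default").
    """

    name: str
    params: Mapping[str, Any]
    provenance: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(self.params) - set(self.provenance)
        if missing:
            raise ValueError(f"parameters without provenance tag: {sorted(missing)}")

    def __getitem__(self, key: str) -> Any:
        return self.params[key]


def _preset(name: str, **kv: tuple[Any, str]) -> Preset:
    return Preset(
        name=name,
        params={k: v for k, (v, _) in kv.items()},
        provenance={k: p for k, (_, p) in kv.items()},
    )


# Motile-fraction gradient along the μ-channel: printed endpoints 67% at the
# gas/liquid interface and 3% at 1.75 mm; intermediate bins log-linear.
_CHANNEL_BIN_EDGES_MM = tuple(np.arange(0.0, 1.76, 0.25))
_CHANNEL_FRACTIONS = tuple(
    float(f) for f in np.exp(np.linspace(math.log(0.67), math.log(0.03), 7))
)

_PRESETS: dict[str, Preset] = {}


def _register(p: Preset) -> Preset:
    _PRESETS[p.name] = p
    return p


_register(_preset(
    "h2_motility",
    mean_speed_um_s=(14.9, "measured"),
    speed_sd_um_s=(9.9, "measured"),
    max_speed_um_s=(43.7, "measured"),
    turn_angle_sd_deg=(30.0, "default"),
    motile_fraction=(1.0, "default"),
    pixel_size_um=(0.33, "default"),
    jitter_px=(0.15, "default"),
    spot_sigma_px=(1.4, "default"),
    spot_amplitude=(0.7, "default"),
    background=(0.1, "default"),
    noise_sigma=(0.03, "default"),
))

_register(_preset(
    "lactate_motility",
    mean_speed_um_s=(3.7, "measured"),
    speed_sd_um_s=(2.3, "measured"),
    max_speed_um_s=(9.5, "measured"),
    turn_angle_sd_deg=(30.0, "default"),
    motile_fraction=(1.0, "default"),
    pixel_size_um=(0.33, "default"),
    jitter_px=(0.15, "default"),
    spot_sigma_px=(1.4, "default"),
    spot_amplitude=(0.7, "default"),
    background=(0.1, "default"),
    noise_sigma=(0.03, "default"),
))

_register(_preset(
    "stationary",
    mean_speed_um_s=(0.0, "default"),
    speed_sd_um_s=(0.0, "default"),
    max_speed_um_s=(0.0, "default"),
    turn_angle_sd_deg=(30.0, "default"),
    motile_fraction=(1.0, "default"),
    pixel_size_um=(0.33, "default"),
    jitter_px=(0.0, "default"),
    spot_sigma_px=(1.4, "default"),
    spot_amplitude=(0.7, "default"),
    background=(0.1, "default"),
    noise_sigma=(0.03, "default"),
))

_register(_preset(
    "channel_day1",
    bin_edges_mm=(_CHANNEL_BIN_EDGES_MM, "measured"),
    motile_fractions=(_CHANNEL_FRACTIONS, "derived"),
    mean_speed_um_s=(14.9, "measured"),
    speed_sd_um_s=(9.9, "measured"),
    max_speed_um_s=(43.7, "measured"),
    turn_angle_sd_deg=(30.0, "default"),
    pixel_size_um=(1.1, "measured"),
    channel_height_px=(640, "default"),
    jitter_px=(0.15, "default"),
    spot_sigma_px=(1.4, "default"),
    spot_amplitude=(0.7, "default"),
    background=(0.1, "default"),
    noise_sigma=(0.03, "default"),
))

_register(_preset(
    "sandstone_geometry",
    width_px=(512, "default"),
    height_px=(512, "default"),
    porosity_target=(0.61, "measured"),
    grain_radius_px=((14, 26), "default"),
    pixel_size_um=(1.1, "measured"),
))

_register(_preset(
    "h2_three_cycle",
    condition=("H2", "measured"),
    cumulative_detachment=((0.11, 0.55, 0.69), "measured"),
    initial_coverage=(0.20, "measured"),
    shutin_growth=(0.0, "measured"),
    gas_pore_fraction=(0.35, "default"),
    porosity_target=(0.61, "measured"),
    pixel_size_um=(1.1, "measured"),
))

_register(_preset(
    "n2_three_cycle",
    condition=("N2", "measured"),
    cumulative_detachment=((0.20, 0.28, 0.31), "derived"),
    initial_coverage=(0.15, "measured"),
    shutin_growth=(0.0087, "measured"),
    gas_pore_fraction=(0.35, "default"),
    porosity_target=(0.61, "measured"),
    pixel_size_um=(1.1, "measured"),
))

_register(_preset(
    "bioclogging",
    clean_gas_saturation=(0.50, "default"),
    saturation_reduction=(0.19, "measured"),
    biofilm_coverage=(0.20, "measured"),
    baseline_biofilm_coverage=(0.02, "default"),
    porosity_target=(0.61, "measured"),
    pixel_size_um=(1.1, "measured"),
))

_register(_preset(
    "lactate_growth",
    initial_cells=(600, "default"),
    growth_rate_percent=(83.44, "measured"),
    growth_window_h=(6.0, "measured"),
    total_hours=(12.0, "default"),
    biofilm_onset_h=(8.0, "measured"),
    biofilm_rate_px_per_h=(3000.0, "default"),
    biofilm_initial_px=(0.0, "default"),
    pixel_size_um=(1.1, "default"),
))

_register(_preset(
    "h2_growth",
    initial_cells=(600, "default"),
    growth_rate_percent=(14.15, "measured"),
    growth_window_h=(4.0, "measured"),
    total_hours=(8.0, "default"),
    biofilm_onset_h=(math.inf, "measured"),
    biofilm_rate_px_per_h=(0.0, "measured"),
    biofilm_initial_px=(1500.0, "default"),
    pixel_size_um=(1.1, "default"),
))


def get_preset(name: str) -> Preset:
    """Look up a preset by name; raises ``KeyError`` listing known names."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(_PRESETS)}") from None


def list_presets() -> list[str]:
    return sorted(_PRESETS)


def _as_preset(preset: Preset | str) -> Preset:
    return get_preset(preset) if isinstance(preset, str) else preset


# --------------------------------------------------------------------------
# Ground-truth containers
# --------------------------------------------------------------------------

@dataclass
class TrackGroundTruth:
    """Exact particle trajectories behind a synthetic video.

    ``positions``: one row per particle-frame (particle, frame, x_px, y_px).
    ``particles``: one row per particle (particle, motile, bin) where ``bin``
    is the spatial distance-bin index or −1 when not applicable.
    Per-step speeds are derived from consecutive positions.
    """

    positions: pd.DataFrame
    particles: pd.DataFrame
    pixel_size_um: float
    fps: float

    def step_speeds(self) -> pd.DataFrame:
        """Per-step speeds (μm/s): particle, frame (step start), speed_um_s."""
        rows = []
        for pid, g in self.positions.groupby("particle", sort=True):
            g = g.sort_values("frame")
            d = np.hypot(np.diff(g["x_px"]), np.diff(g["y_px"]))
            rows.append(pd.DataFrame({
                "particle": pid,
                "frame": g["frame"].to_numpy()[:-1],
                "speed_um_s": d * self.pixel_size_um * self.fps,
            }))
        if not rows:
            return pd.DataFrame(columns=["particle", "frame", "speed_um_s"])
        return pd.concat(rows, ignore_index=True)

    def mean_step_speed(self) -> float:
        return float(self.step_speeds()["speed_um_s"].mean())


@dataclass
class ZStackGroundTruth:
    """Per-blob voxel counts and per-slice areas for a synthetic Z-stack."""

    voxel_counts: list[int]
    slice_areas: list[np.ndarray]     # per blob: area per slice (px)
    overlaps: list[tuple[int, int]]   # blob index pairs sharing voxels
    label_volume: np.ndarray          # 0 background, 1..n blobs (first wins)
    distractor_voxels: list[tuple[int, int, int]]


@dataclass
class DetachmentSeries:
    """Rendered pore-network series plus exact phase-map ground truth."""

    frames: list[ImageFrame]
    phase_maps: list[PhaseMap]
    grain_mask: np.ndarray
    reference_index: int
    cycle_end_indices: list[int]
    gt_normalized_coverage: np.ndarray
    preset: Preset


# --------------------------------------------------------------------------
# Speed distribution: moment-matched truncated normal
# --------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _truncnorm_shape(mean: float, sd: float, lower: float, upper: float):
    """(loc, scale) of a normal truncated to [lower, upper] whose *truncated*
    mean and SD equal the requested values.

    The printed speed statistics are sample statistics of the observed
    (bounded) speeds, so the preset must reproduce them after truncation;
    using the printed mean/SD directly as loc/scale would bias the realised
    mean upward by several percent.
    """
    if sd == 0.0:
        return mean, 0.0

    def residual(p):
        loc, log_scale = p
        scale = math.exp(log_scale)
        a, b = (lower - loc) / scale, (upper - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(residual, x0=[mean, math.log(sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(
            f"no truncated normal matches mean={mean}, sd={sd} on [{lower}, {upper}]"
        )
    loc, log_scale = sol.x
    return float(loc), float(math.exp(log_scale))


def _draw_speeds(preset: Preset, n: int, rng: np.random.Generator) -> np.ndarray:
    """n per-step speeds (μm/s) from the preset's truncated normal."""
    mean = preset["mean_speed_um_s"]
    sd = preset["speed_sd_um_s"]
    upper = preset["max_speed_um_s"]
    if upper == 0.0 or (mean == 0.0 and sd == 0.0):
        return np.zeros(n)
    loc, scale = _truncnorm_shape(mean, sd, 0.0, upper)
    a, b = (0.0 - loc) / scale, (upper - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


# --------------------------------------------------------------------------
# Rendering helpers
# --------------------------------------------------------------------------

def _add_spots(canvas: np.ndarray, xs, ys, amplitude: float, sigma: float) -> None:
    """Add 2D Gaussian intensity bumps at sub-pixel centres, in place."""
    h, w = canvas.shape
    half = max(3, int(math.ceil(4 * sigma)))
    for x, y in zip(xs, ys):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(0, cx - half), min(w, cx + half + 1)
        y0, y1 = max(0, cy - half), min(h, cy + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        canvas[y0:y1, x0:x1] += amplitude * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)
        )


def _finish_frame(canvas: np.ndarray, noise_sigma: float,
                  rng: np.random.Generator, invert: bool) -> np.ndarray:
    if invert:
        canvas = 1.0 - canvas
    if noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, noise_sigma, canvas.shape)
    return np.clip(canvas, 0.0, 1.0)


def _place_separated(n: int, lo: np.ndarray, hi: np.ndarray, min_sep: float,
                     rng: np.random.Generator, max_tries: int = 5000) -> np.ndarray:
    """n points uniform in the box [lo, hi] with pairwise distance ≥ min_sep.

    Sequential rejection: earlier points are unaffected by later ones.
    Raises if the density is too high, naming the count that did fit.
    """
    pts = np.empty((0, 2))
    for i in range(n):
        for _ in range(max_tries):
            cand = rng.uniform(lo, hi)
            if len(pts) == 0 or np.min(np.hypot(*(pts - cand).T)) >= min_sep:
                pts = np.vstack([pts, cand])
                break
        else:
            raise ValueError(
                f"cell density too high for separation {min_sep:.1f} px: "
                f"only {i} of {n} cells fit"
            )
    return pts


# --------------------------------------------------------------------------
# Pore network
# --------------------------------------------------------------------------

def _paint_disks(shape: tuple[int, int], centers: np.ndarray,
                 radii: np.ndarray) -> np.ndarray:
    """Rasterise disks (pixel-centre-in-circle) into a boolean mask."""
    h, w = shape
    mask = np.zeros(shape, bool)
    for (cy, cx), r in zip(centers, radii):
        y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
        x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


def generate_pore_network(
    width_px: int = 512,
    height_px: int = 512,
    grain_count: int | None = None,
    grain_radius_px: tuple[float, float] = (14, 26),
    porosity_target: float = 0.61,
    seed: int = 0,
    tolerance: float = 0.02,
) -> tuple[np.ndarray, float]:
    """Random-disk grain mask tuned to a target porosity.

    Grains are overlapping disks with radii uniform in ``grain_radius_px``;
    grains are greedily removed (or added) until the achieved porosity
    (pore pixels / total pixels) is within ``tolerance`` of the target.
    Returns ``(grain_mask, achieved_porosity)`` with True = grain.

    Raises ``ValueError`` when the target cannot be reached (e.g. grain
    radii so large that removing/adding one grain always overshoots).
    """
    if not 0.0 < porosity_target < 1.0:
        raise ValueError("porosity_target must be in (0, 1)")
    if width_px < 64 or height_px < 64:
        raise ValueError("dimensions must be >= 64 px")
    if grain_count == 0:
        return np.zeros((height_px, width_px), bool), 1.0

    rng = np.random.default_rng([seed, 101])
    area = width_px * height_px
    r_lo, r_hi = grain_radius_px
    mean_disk = math.pi * ((r_lo + r_hi) / 2) ** 2
    if grain_count is None:
        # overshoot; tuning removes the excess
        grain_count = int(1.4 * area * (1 - porosity_target) / mean_disk) + 1

    centers = rng.uniform([0, 0], [height_px, width_px], (grain_count, 2))
    radii = list(rng.uniform(r_lo, r_hi, grain_count))
    centers = [tuple(c) for c in centers]

    def porosity_of() -> float:
        m = _paint_disks((height_px, width_px), np.array(centers), np.array(radii))
        return 1.0 - m.mean()

    # greedy removal/addition; once inside the band, grains sized to the
    # remaining error (still within the radius distribution) centre the
    # achieved porosity on the target rather than on the band edge
    fine_tol = min(tolerance, max(0.005, 2 * math.pi * r_lo**2 / area))
    best_p, best_state = None, None
    for _ in range(4 * grain_count + 200):
        p = porosity_of()
        if best_p is None or abs(p - porosity_target) < abs(best_p - porosity_target):
            best_p, best_state = p, (list(centers), list(radii))
        if abs(p - porosity_target) <= fine_tol:
            mask = _paint_disks((height_px, width_px), np.array(centers),
                                np.array(radii))
            return mask, 1.0 - mask.mean()
        need_px = abs(p - porosity_target) * area
        r_need = min(max(math.sqrt(need_px / math.pi), r_lo), r_hi)
        if p < porosity_target:
            if not centers:
                break
            # too much grain: drop the disk whose area best matches the error
            i = int(np.argmin([abs(math.pi * r * r - need_px) for r in radii]))
            centers.pop(i)
            radii.pop(i)
        else:
            centers.append(tuple(rng.uniform([0, 0], [height_px, width_px])))
            radii.append(r_need)
    if best_p is not None and abs(best_p - porosity_target) <= tolerance:
        centers, radii = best_state
        mask = _paint_disks((height_px, width_px), np.array(centers),
                            np.array(radii))
        return mask, 1.0 - mask.mean()
    raise ValueError(
        f"porosity target {porosity_target} ± {tolerance} unreachable with "
        f"grain radii {grain_radius_px}"
    )


# --------------------------------------------------------------------------
# Motility videos
# --------------------------------------------------------------------------

def _walk(
    start: np.ndarray,
    n_steps: int,
    speeds_px: np.ndarray,
    turn_sd_rad: float,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Persistent random walk with reflecting bounds.

    A step that would leave the box has the offending component flipped
    *before* the step is taken, so every recorded consecutive-position
    distance equals the drawn step length exactly.
    """
    pos = np.empty((n_steps + 1, 2))
    pos[0] = start
    heading = rng.uniform(0, 2 * math.pi)
    for t in range(n_steps):
        heading += rng.normal(0.0, turn_sd_rad)
        dx = speeds_px[t] * math.cos(heading)
        dy = speeds_px[t] * math.sin(heading)
        x, y = pos[t]
        if not (bounds_lo[0] <= x + dx <= bounds_hi[0]):
            dx = -dx
        if not (bounds_lo[1] <= y + dy <= bounds_hi[1]):
            dy = -dy
        heading = math.atan2(dy, dx) if (dx or dy) else heading
        pos[t + 1] = (min(max(x + dx, bounds_lo[0]), bounds_hi[0]),
                      min(max(y + dy, bounds_lo[1]), bounds_hi[1]))
    return pos


def _render_video(
    all_pos: np.ndarray,  # (n_cells, n_frames, 2) x,y
    frame_shape: tuple[int, int],
    preset: Preset,
    fps: float,
    seed: int,
    invert: bool,
) -> VideoSequence:
    n_frames = all_pos.shape[1]
    frames = []
    for t in range(n_frames):
        canvas = np.full(frame_shape, preset["background"], float)
        _add_spots(canvas, all_pos[:, t, 0], all_pos[:, t, 1],
                   preset["spot_amplitude"], preset["spot_sigma_px"])
        noise_rng = np.random.default_rng([seed, 7, t])
        px = _finish_frame(canvas, preset["noise_sigma"], noise_rng, invert)
        frames.append(ImageFrame(px, preset["pixel_size_um"], timestamp_s=t / fps))
    return VideoSequence(frames, fps=fps)


def simulate_motility_video(
    preset: Preset | str,
    duration_s: float = 5.0,
    fps: float = 20.0,
    n_cells: int = 200,
    frame_shape: tuple[int, int] = (1024, 1024),
    seed: int = 0,
    invert: bool = False,
) -> tuple[VideoSequence, TrackGroundTruth]:
    """Video of swimming cells with exact trajectory ground truth.

    Motile cells perform persistent random walks (per-step speeds from the
    preset's moment-matched truncated normal, turning-angle SD from the
    preset); immotile cells jitter with sub-resolution amplitude.  Cells are
    rendered as Gaussian intensity bumps over a flat background plus
    additive Gaussian noise.
    """
    preset = _as_preset(preset)
    n_frames = int(round(duration_s * fps))
    if n_frames < 2:
        raise ValueError("duration_s × fps must give at least 2 frames")

    h, w = frame_shape
    min_sep = 4 * (2 * preset["spot_sigma_px"] * 2)  # 4× rendered spot diameter
    margin = 10.0
    place_rng = np.random.default_rng([seed, 11])
    starts = _place_separated(
        n_cells, np.array([margin, margin]), np.array([w - margin, h - margin]),
        min_sep, place_rng,
    )

    n_motile = int(round(preset["motile_fraction"] * n_cells))
    dt = 1.0 / fps
    px_per_um = 1.0 / preset["pixel_size_um"]
    turn_sd = math.radians(preset["turn_angle_sd_deg"])
    lo = np.array([2.0, 2.0])
    hi = np.array([w - 3.0, h - 3.0])

    all_pos = np.empty((n_cells, n_frames, 2))
    motile = np.zeros(n_cells, bool)
    for i in range(n_cells):
        rng_i = np.random.default_rng([seed, 2, i])
        if i < n_motile:
            motile[i] = True
            speeds_px = _draw_speeds(preset, n_frames - 1, rng_i) * dt * px_per_um
            all_pos[i] = _walk(starts[i], n_frames - 1, speeds_px, turn_sd, lo, hi, rng_i)
        else:
            jit = rng_i.normal(0.0, preset["jitter_px"], (n_frames, 2))
            all_pos[i] = np.clip(starts[i] + jit, lo, hi)

    video = _render_video(all_pos, frame_shape, preset, fps, seed, invert)
    gt = _ground_truth_from_positions(all_pos, motile, np.full(n_cells, -1),
                                      preset["pixel_size_um"], fps)
    return video, gt


def _ground_truth_from_positions(all_pos, motile, bins, pixel_size_um, fps):
    n_cells, n_frames, _ = all_pos.shape
    pos = pd.DataFrame({
        "particle": np.repeat(np.arange(n_cells), n_frames),
        "frame": np.tile(np.arange(n_frames), n_cells),
        "x_px": all_pos[:, :, 0].ravel(),
        "y_px": all_pos[:, :, 1].ravel(),
    })
    particles = pd.DataFrame({
        "particle": np.arange(n_cells),
        "motile": motile,
        "bin": bins,
    })
    return TrackGroundTruth(pos, particles, pixel_size_um, fps)


def simulate_channel_gradient(
    preset: Preset | str,
    bin_edges_mm: Sequence[float] | None = None,
    cells_per_bin: int = 100,
    duration_s: float = 5.0,
    fps: float = 20.0,
    seed: int = 0,
) -> tuple[VideoSequence, TrackGroundTruth]:
    """μ-channel scene: motile fraction decays with distance from the interface.

    Each distance bin along the channel receives ``cells_per_bin`` cells of
    which ``round(fraction × cells_per_bin)`` are motile (fractions from the
    preset, log-linear between the printed endpoints).  Cells reflect at
    their bin boundaries so ground-truth bin membership is exact.
    """
    preset = _as_preset(preset)
    edges_mm = np.asarray(
        bin_edges_mm if bin_edges_mm is not None else preset["bin_edges_mm"], float
    )
    if np.any(np.diff(edges_mm) <= 0):
        raise ValueError("bin_edges_mm must be strictly increasing")
    fractions = np.asarray(preset["motile_fractions"], float)
    if len(fractions) != len(edges_mm) - 1:
        raise ValueError("need one motile fraction per bin")
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("motile fractions must lie in [0, 1]")

    n_frames = int(round(duration_s * fps))
    px = preset["pixel_size_um"]
    edges_px = edges_mm * 1000.0 / px
    w = int(math.ceil(edges_px[-1])) + 4
    h = int(preset["channel_height_px"])
    dt = 1.0 / fps
    turn_sd = math.radians(preset["turn_angle_sd_deg"])
    min_sep = 4 * (2 * preset["spot_sigma_px"] * 2)  # 4× rendered spot diameter

    n_bins = len(fractions)
    n_cells = n_bins * cells_per_bin
    all_pos = np.empty((n_cells, n_frames, 2))
    motile = np.zeros(n_cells, bool)
    bin_of = np.empty(n_cells, int)

    cell = 0
    for j in range(n_bins):
        x0, x1 = edges_px[j], edges_px[j + 1]
        lo = np.array([x0 + 3.0, 3.0])
        hi = np.array([x1 - 3.0, h - 4.0])
        place_rng = np.random.default_rng([seed, 11, j])
        starts = _place_separated(cells_per_bin, lo, hi, min_sep, place_rng)
        n_motile = int(round(fractions[j] * cells_per_bin))
        for i in range(cells_per_bin):
            rng_i = np.random.default_rng([seed, 2, j, i])
            if i < n_motile:
                motile[cell] = True
                speeds_px = _draw_speeds(preset, n_frames - 1, rng_i) * dt / px
                all_pos[cell] = _walk(starts[i], n_frames - 1, speeds_px,
                                      turn_sd, lo, hi, rng_i)
            else:
                jit = rng_i.normal(0.0, preset["jitter_px"], (n_frames, 2))
                all_pos[cell] = np.clip(starts[i] + jit, lo, hi)
            bin_of[cell] = j
            cell += 1

    video = _render_video(all_pos, (h, w), preset, fps, seed, invert=False)
    gt = _ground_truth_from_positions(all_pos, motile, bin_of, px, fps)
    return video, gt


# --------------------------------------------------------------------------
# Z-stacks
# --------------------------------------------------------------------------

def simulate_biofilm_zstack(
    blob_specs: Sequence[Mapping[str, Sequence[float]]],
    n_slices: int = 43,
    z_step_um: float = 0.6,
    frame_shape: tuple[int, int] = (128, 128),
    pixel_size_um: float = 0.11,
    noise_sigma: float = 0.02,
    n_distractors: int = 20,
    seed: int = 0,
) -> tuple[ImageStack, ZStackGroundTruth]:
    """Z-stack of ellipsoidal biofilm blobs rendered darker than background.

    Each spec is ``{"center": (x, y, z), "semi_axes": (a, b, c)}`` in voxel
    units (z in slice index units).  Blobs are filled ellipsoids evaluated
    at voxel centres; isolated single-voxel "cells" are added as
    distractors.  Overlapping blobs are allowed but flagged in the ground
    truth.
    """
    if n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    h, w = frame_shape
    vol_label = np.zeros((n_slices, h, w), np.int32)
    zz, yy, xx = np.mgrid[0:n_slices, 0:h, 0:w]
    counts, areas = [], []
    masks = []
    for bi, spec in enumerate(blob_specs, start=1):
        cx, cy, cz = spec["center"]
        a, b, c = spec["semi_axes"]
        if not (a <= cx <= w - 1 - a and b <= cy <= h - 1 - b and c <= cz <= n_slices - 1 - c):
            raise ValueError(f"blob {bi - 1} does not fit inside the volume")
        inside = (((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
                  + ((zz - cz) / c) ** 2) <= 1.0
        masks.append(inside)
        counts.append(int(inside.sum()))
        areas.append(inside.sum(axis=(1, 2)))
        vol_label[(vol_label == 0) & inside] = bi
    overlaps = [
        (i, j)
        for i in range(len(masks))
        for j in range(i + 1, len(masks))
        if np.any(masks[i] & masks[j])
    ]

    rng = np.random.default_rng([seed, 31])
    distractors = []
    occupied = vol_label > 0
    for _ in range(n_distractors):
        for _ in range(200):
            z = int(rng.integers(0, n_slices))
            y = int(rng.integers(1, h - 1))
            x = int(rng.integers(1, w - 1))
            if not occupied[max(0, z - 1):z + 2, y - 1:y + 2, x - 1:x + 2].any():
                distractors.append((z, y, x))
                occupied[z, y, x] = True
                break

    slices = []
    for k in range(n_slices):
        canvas = np.full((h, w), 0.8)
        canvas[vol_label[k] > 0] = 0.25
        for (z, y, x) in distractors:
            if z == k:
                canvas[y, x] = 0.25
        noise_rng = np.random.default_rng([seed, 7, k])
        pxls = _finish_frame(canvas, noise_sigma, noise_rng, invert=False)
        slices.append(ImageFrame(pxls, pixel_size_um, timestamp_s=0.0))

    stack = ImageStack(slices, z_step_um=z_step_um)
    gt = ZStackGroundTruth(counts, areas, overlaps, vol_label, distractors)
    return stack, gt


# --------------------------------------------------------------------------
# Pore-network detachment series
# --------------------------------------------------------------------------

def _biofilm_deposition_order(grain_mask: np.ndarray,
                              rng: np.random.Generator) -> np.ndarray:
    """Flat pixel indices of grain-hugging biofilm sites, in deposition order.

    Biofilm coats grains: each grain (in shuffled order) contributes the pore
    pixels nearest to it out to a random coat thickness, ordered inner to
    outer.  Prefixes of the returned order are nested growing biofilms whose
    connected components are per-grain coats.
    """
    dist, (iy, ix) = ndimage.distance_transform_edt(~grain_mask, return_indices=True)
    grains = _skmeasure.label(grain_mask, connectivity=2)
    nearest = grains[iy, ix]  # label of nearest grain for every pixel
    n_grains = int(grains.max())
    if n_grains == 0:
        return np.empty(0, np.int64)
    order = rng.permutation(np.arange(1, n_grains + 1))
    thickness = rng.uniform(2.0, 6.0, n_grains + 1)

    flat_dist = dist.ravel()
    flat_near = nearest.ravel()
    pore = ~grain_mask.ravel()
    chunks = []
    for extra in (0.0, 2.0, 4.0):  # widen coats if early passes fall short
        for g in order:
            sel = np.flatnonzero(pore & (flat_near == g)
                                 & (flat_dist <= thickness[g] + extra)
                                 & (flat_dist > (thickness[g] + extra - 2.0 if extra else 0.0)))
            sel = sel[np.lexsort((sel, flat_dist[sel]))]
            chunks.append(sel)
    out = np.concatenate(chunks) if chunks else np.empty(0, np.int64)
    _, first = np.unique(out, return_index=True)
    return out[np.sort(first)]


def _component_removal_order(biofilm_flat: np.ndarray, shape: tuple[int, int],
                             grain_mask: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
    """Removal queue: whole connected biofilm components in random order,
    each component's pixels outermost (farthest from grain) first."""
    mask = np.zeros(shape, bool)
    mask.ravel()[biofilm_flat] = True
    lab = _skmeasure.label(mask, connectivity=2)
    dist = ndimage.distance_transform_edt(~grain_mask)
    n = int(lab.max())
    comp_order = rng.permutation(np.arange(1, n + 1))
    flat_lab = lab.ravel()
    flat_dist = dist.ravel()
    queue = []
    for c in comp_order:
        sel = np.flatnonzero(flat_lab == c)
        sel = sel[np.lexsort((sel, -flat_dist[sel]))]
        queue.append(sel)
    return np.concatenate(queue) if queue else np.empty(0, np.int64)


def _gas_mask(grain_mask: np.ndarray, biofilm: np.ndarray, n_gas: int) -> np.ndarray:
    """Gas occupies the ``n_gas`` pore∖biofilm pixels farthest from grain
    (non-wetting phase fills the largest pore bodies); deterministic
    tie-break by raster order."""
    dist = ndimage.distance_transform_edt(~grain_mask).ravel()
    candidates = np.flatnonzero(~grain_mask.ravel() & ~biofilm.ravel())
    if n_gas > len(candidates):
        raise ValueError("gas fraction exceeds available pore space")
    order = candidates[np.lexsort((candidates, -dist[candidates]))]
    mask = np.zeros(grain_mask.size, bool)
    mask[order[:n_gas]] = True
    return mask.reshape(grain_mask.shape)


_PHASE_INTENSITY = {GRAIN: 0.35, LIQUID: 0.55, GAS: 0.92, BIOFILM: 0.15}


def _render_phase_map(labels: np.ndarray, noise_sigma: float,
                      rng: np.random.Generator) -> np.ndarray:
    canvas = np.empty(labels.shape, float)
    for phase, val in _PHASE_INTENSITY.items():
        canvas[labels == phase] = val
    return _finish_frame(canvas, noise_sigma, rng, invert=False)


def _phase_labels(grain_mask, biofilm, gas) -> np.ndarray:
    labels = np.full(grain_mask.shape, LIQUID, np.uint8)
    labels[gas] = GAS
    labels[biofilm] = BIOFILM
    labels[grain_mask] = GRAIN
    return labels


def simulate_detachment_series(
    preset: Preset | str,
    frames_per_phase: int = 8,
    noise_sigma: float = 0.02,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
) -> DetachmentSeries:
    """Multi-cycle gas-injection series over a pore network.

    Timeline: one growth phase (biofilm coverage ramps up to the reference
    coverage), then three cycles of (injection, shut-in).  After injection
    ``k`` the cumulative detached area fraction equals the preset schedule to
    the nearest pixel; detachment removes randomly chosen biofilm components
    (outermost pixels first within the last, partially removed component).
    Gas appears at the first injection and occupies the preset's pore-space
    fraction.  The N₂ preset inserts its small growth blip during the first
    shut-in.  Ground-truth phase maps are stored for every frame.
    """
    preset = _as_preset(preset)
    schedule = np.asarray(preset["cumulative_detachment"], float)
    if np.any(np.diff(schedule) < 0) or np.any((schedule < 0) | (schedule > 1)):
        raise ValueError("cumulative detachment schedule must be non-decreasing in [0, 1]")

    grain_mask, _ = generate_pore_network(
        shape[1], shape[0], porosity_target=preset["porosity_target"],
        seed=seed, grain_radius_px=(14, 26),
    )
    pore_px = int((~grain_mask).sum())
    rng = np.random.default_rng([seed, 41])
    deposition = _biofilm_deposition_order(grain_mask, rng)

    c_ref = int(round(preset["initial_coverage"] * pore_px))
    blip_px = int(round(preset["shutin_growth"] * c_ref))
    if len(deposition) < c_ref + blip_px:
        raise ValueError("pore network too tight to deposit the requested biofilm")

    n_gas = int(round(preset["gas_pore_fraction"] * pore_px))
    px_size = preset["pixel_size_um"]
    n_cycles = len(schedule)

    # --- phase plan -------------------------------------------------------
    # growth, then (injection, shut-in) per cycle; frames_per_phase frames each
    frames: list[ImageFrame] = []
    phase_maps: list[PhaseMap] = []
    gt_norm: list[float] = []

    def emit(biofilm_flat_count_set: np.ndarray, with_gas: bool, t_index: int) -> None:
        biofilm = np.zeros(shape, bool)
        biofilm.ravel()[biofilm_flat_count_set] = True
        gas = (_gas_mask(grain_mask, biofilm, n_gas)
               if with_gas else np.zeros(shape, bool))
        labels = _phase_labels(grain_mask, biofilm, gas)
        noise_rng = np.random.default_rng([seed, 7, t_index])
        pxls = _render_phase_map(labels, noise_sigma, noise_rng)
        frames.append(ImageFrame(pxls, px_size, timestamp_s=float(t_index)))
        phase_maps.append(PhaseMap(labels, px_size, timestamp_s=float(t_index)))
        gt_norm.append(len(biofilm_flat_count_set) / c_ref)

    t = 0
    # growth phase: ramp from 60% of reference to the reference coverage
    for j in range(frames_per_phase):
        frac = 0.6 + 0.4 * (j + 1) / frames_per_phase
        emit(deposition[: int(round(frac * c_ref))], with_gas=False, t_index=t)
        t += 1
    reference_index = t - 1

    current = deposition[:c_ref].copy()
    removal_queue = list(_component_removal_order(current, shape, grain_mask, rng))
    grown_pool = deposition[c_ref: c_ref + blip_px]
    cycle_end_indices: list[int] = []

    for k in range(n_cycles):
        # injection: detach down to the schedule target, exact to a pixel
        target = int(round((1.0 - schedule[k]) * c_ref))
        need = len(current) - target
        removed: list[int] = []
        cur_set = set(current.tolist())
        while need > 0 and removal_queue:
            pix = removal_queue.pop(0)
            if pix in cur_set:
                removed.append(pix)
                cur_set.discard(pix)
                need -= 1
        current = np.array(sorted(cur_set), np.int64)
        for _ in range(frames_per_phase):
            emit(current, with_gas=True, t_index=t)
            t += 1
        cycle_end_indices.append(t - 1)

        # shut-in: optional growth blip during the first shut-in (N₂ control)
        if k == 0 and blip_px > 0:
            grown_sorted = grown_pool[np.argsort(grown_pool)]
            for j in range(frames_per_phase):
                add = grown_sorted[: int(round(blip_px * (j + 1) / frames_per_phase))]
                emit(np.union1d(current, add), with_gas=True, t_index=t)
                t += 1
            current = np.union1d(current, grown_sorted)
            removal_queue = grown_sorted[::-1].tolist() + removal_queue
        else:
            for _ in range(frames_per_phase):
                emit(current, with_gas=True, t_index=t)
                t += 1

    return DetachmentSeries(
        frames=frames,
        phase_maps=phase_maps,
        grain_mask=grain_mask,
        reference_index=reference_index,
        cycle_end_indices=cycle_end_indices,
        gt_normalized_coverage=np.asarray(gt_norm),
        preset=preset,
    )


def simulate_paired_saturation(
    preset: Preset | str = "bioclogging",
    noise_sigma: float = 0.02,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
) -> tuple[ImageFrame, ImageFrame, np.ndarray, PhaseMap, PhaseMap]:
    """Paired scenes isolating the bioclogging effect on gas saturation.

    Scene A: bacterial solution with trace biofilm, gas at the preset's clean
    saturation.  Scene B: lactate-grown biofilm (preset coverage) whose
    clogging reduces gas saturation by the preset's relative reduction; the
    gas pixel counts are constructed so the ground-truth relative reduction
    equals the preset value to the nearest pixel.  Both scenes share one
    grain mask.  Returns (frame_clean, frame_biofilm, grain_mask,
    phasemap_clean, phasemap_biofilm).
    """
    preset = _as_preset(preset)
    grain_mask, _ = generate_pore_network(
        shape[1], shape[0], porosity_target=preset["porosity_target"],
        seed=seed, grain_radius_px=(14, 26),
    )
    pore_px = int((~grain_mask).sum())
    rng = np.random.default_rng([seed, 41])
    deposition = _biofilm_deposition_order(grain_mask, rng)

    n_base = int(round(preset["baseline_biofilm_coverage"] * pore_px))
    n_full = int(round(preset["biofilm_coverage"] * pore_px))
    n_gas_a = int(round(preset["clean_gas_saturation"] * pore_px))
    n_gas_b = int(round((1.0 - preset["saturation_reduction"]) * n_gas_a))

    px_size = preset["pixel_size_um"]
    out = []
    for i, (n_bio, n_gas) in enumerate(((n_base, n_gas_a), (n_full, n_gas_b))):
        biofilm = np.zeros(shape, bool)
        biofilm.ravel()[deposition[:n_bio]] = True
        gas = _gas_mask(grain_mask, biofilm, n_gas)
        labels = _phase_labels(grain_mask, biofilm, gas)
        noise_rng = np.random.default_rng([seed, 7, i])
        pxls = _render_phase_map(labels, noise_sigma, noise_rng)
        out.append((ImageFrame(pxls, px_size, timestamp_s=float(i)),
                    PhaseMap(labels, px_size, timestamp_s=float(i))))
    (fa, ma), (fb, mb) = out
    return fa, fb, grain_mask, ma, mb


# --------------------------------------------------------------------------
# Growth series (μ-dish overview frames)
# --------------------------------------------------------------------------

def _growth_counts(preset: Preset, times_h: np.ndarray) -> np.ndarray:
    """True cell count per time point: exponential growth over the printed
    window (reaching exactly the printed relative increase), then plateau."""
    n0 = preset["initial_cells"]
    factor = 1.0 + preset["growth_rate_percent"] / 100.0
    window = preset["growth_window_h"]
    counts = n0 * factor ** (np.minimum(times_h, window) / window)
    return np.round(counts).astype(int)


def simulate_growth_series(
    preset: Preset | str,
    n_frames: int | None = None,
    frame_shape: tuple[int, int] = (1024, 1024),
    noise_sigma: float = 0.03,
    seed: int = 0,
) -> tuple[list[ImageFrame], pd.DataFrame]:
    """Hourly overview frames whose true cell count follows a growth curve.

    Cells render as small gray dips, biofilm as extended dark blobs on a
    bright background (transmitted-light contrast).  Cell positions are
    re-sampled each frame (counts, not identities, are the measurand).
    Returns the frames and a ground-truth table (frame, time_h, n_cells,
    biofilm_area_px).
    """
    preset = _as_preset(preset)
    total_h = preset["total_hours"]
    if n_frames is None:
        n_frames = int(total_h) + 1
    times_h = np.linspace(0.0, total_h, n_frames)
    counts = _growth_counts(preset, times_h)
    if np.any(counts < 0):
        raise ValueError("negative cell counts in trajectory")

    h, w = frame_shape
    px_size = preset["pixel_size_um"]
    onset = preset["biofilm_onset_h"]
    rate = preset["biofilm_rate_px_per_h"]
    bio0 = preset["biofilm_initial_px"]

    # biofilm blobs: fixed anchor disks grown to the target area per frame
    anchor_rng = np.random.default_rng([seed, 51])
    anchors = anchor_rng.uniform([80, 80], [h - 80, w - 80], (4, 2))

    frames = []
    gt_rows = []
    for fi, t_h in enumerate(times_h):
        target_bio = bio0 + (rate * (t_h - onset) if t_h >= onset else 0.0)
        bio_mask = np.zeros((h, w), bool)
        if target_bio > 0:
            per_blob = target_bio / len(anchors)
            radius = math.sqrt(per_blob / math.pi)
            bio_mask = _paint_disks((h, w), anchors, np.full(len(anchors), radius))
        bio_area = int(bio_mask.sum())

        canvas = np.full((h, w), 0.85)
        canvas[bio_mask] = 0.15
        # cells live in the solution, away from biofilm
        place_rng = np.random.default_rng([seed, 3, fi])
        margin = 8.0
        keep_out = ndimage.binary_dilation(bio_mask, iterations=6)
        pts = []
        tries = 0
        while len(pts) < counts[fi]:
            tries += 1
            if tries > 500 * counts[fi] + 1000:
                raise ValueError("frame too crowded for requested cell count")
            cand = place_rng.uniform([margin, margin], [w - margin, h - margin])
            if keep_out[int(cand[1]), int(cand[0])]:
                continue
            if pts and np.min(np.hypot(*(np.array(pts) - cand).T)) < 9.0:
                continue
            pts.append(cand)
        pts = np.asarray(pts).reshape(-1, 2)
        _add_spots(canvas, pts[:, 0], pts[:, 1], amplitude=-0.4, sigma=1.3)
        noise_rng = np.random.default_rng([seed, 7, fi])
        pxls = _finish_frame(canvas, noise_sigma, noise_rng, invert=False)
        frames.append(ImageFrame(pxls, px_size, timestamp_s=t_h * 3600.0))
        gt_rows.append({"frame": fi, "time_h": t_h, "n_cells": int(counts[fi]),
                        "biofilm_area_px": bio_area})

    return frames, pd.DataFrame(gt_rows)
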