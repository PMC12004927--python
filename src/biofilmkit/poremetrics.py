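"""Pore-network state quantification.

A microfluidic pore network holds up to four phases at once: silicon
grains (static), aqueous solution, injected gas (H₂ or N₂) and
grain-attached biofilm.  Per frame the non-grain pixels are split into
three intensity bands by multi-Otsu thresholding; the band→phase map is a
configuration choice (for the scenes this package renders, gas is
brightest and biofilm darkest).  From the resulting phase maps come the
study's pore-scale metrics: porosity, biofilm pore-space coverage,
normalized coverage across injection cycles, cumulative and incremental
detachment, gas saturation and its reduction by bioclogging, trapped-gas
ganglia shrinkage, and gas–liquid interface displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as _skmeasure

from . import segment as _segment

__all__ = [
    "GRAIN", "LIQUID", "GAS", "BIOFILM",
    "PhaseMap", "CoverageSeries",
    "classify_phases", "porosity", "biofilm_coverage", "gas_saturation",
    "saturation_reduction", "normalize_series", "cumulative_detachment",
    "ganglia_table", "interface_displacement",
]

GRAIN, LIQUID, GAS, BIOFILM = 0, 1, 2, 3
_PHASE_NAMES = {GRAIN: "GRAIN", LIQUID: "LIQUID", GAS: "GAS", BIOFILM: "BIOFILM"}

# darkest → brightest intensity band to phase (transmitted-light default:
# biofilm darkest, solution middle, gas brightest); a config key, not physics
DEFAULT_BAND_TO_PHASE = (BIOFILM, LIQUID, GAS)


@dataclass
class PhaseMap:
    """Per-pixel categorical phase labels over the pore network."""

    labels: np.ndarray
    pixel_size_um: float
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        valid = np.isin(self.labels, list(_PHASE_NAMES))
        if not valid.all():
            raise ValueError("phase labels must be GRAIN/LIQUID/GAS/BIOFILM")

    def fraction(self, phase: int) -> float:
        """Fraction of *pore* (non-grain) pixels carrying ``phase``."""
        pore = self.labels != GRAIN
        n_pore = int(pore.sum())
        if n_pore == 0:
            raise ValueError("phase map has no pore pixels")
        return float((self.labels == phase).sum()) / n_pore


@dataclass
class CoverageSeries:
    """Biofilm pore-space coverage over time with cycle annotations."""

    timestamps: np.ndarray
    coverage: np.ndarray
    condition: str = ""
    cycle_end_indices: list[int] = field(default_factory=list)
    normalized: np.ndarray | None = None
    reference_index: int | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, float)
        self.coverage = np.asarray(self.coverage, float)
        if len(self.timestamps) != len(self.coverage):
            raise ValueError("timestamps and coverage lengths differ")
        if np.any((self.coverage < 0) | (self.coverage > 1)):
            raise ValueError("coverage must lie in [0, 1]")


def classify_phases(
    frame,
    grain_mask: np.ndarray,
    thresholds: np.ndarray | None = None,
    band_to_phase: tuple[int, int, int] = DEFAULT_BAND_TO_PHASE,
    n_bins: int = 256,
) -> PhaseMap:
    """Split the non-grain pixels of a frame into phases.

    Thresholds default to 3-class multi-Otsu computed on the non-grain
    pixels only; pass explicit ``thresholds`` (length 2, ascending) when the
    histogram is degenerate.  ``band_to_phase`` maps the (darkest, middle,
    brightest) bands onto phases.

    Raises ``ValueError`` when fewer than three intensity populations exist.
    """
    pixels = frame.pixels if hasattr(frame, "pixels") else np.asarray(frame, float)
    grain_mask = np.asarray(grain_mask, bool)
    if grain_mask.shape != pixels.shape:
        raise ValueError("grain_mask shape does not match frame")
    labels = np.full(pixels.shape, GRAIN, np.uint8)
    pore_pixels = pixels[~grain_mask]
    if pore_pixels.size:
        if thresholds is None:
            hist = _segment.intensity_histogram(pore_pixels, n_bins)
            try:
                thresholds = _segment.multi_otsu_thresholds(hist, n_classes=3)
            except ValueError as exc:
                raise ValueError(
                    f"degenerate pore-intensity histogram ({exc}); "
                    "supply manual thresholds"
                ) from None
        bands = np.searchsorted(np.asarray(thresholds, float), pore_pixels, side="left")
        phase_of_band = np.asarray(band_to_phase, np.uint8)
        labels[~grain_mask] = phase_of_band[bands]
    ts = getattr(frame, "timestamp_s", 0.0)
    px = getattr(frame, "pixel_size_um", 1.0)
    return PhaseMap(labels, pixel_size_um=px, timestamp_s=ts)


def porosity(grain_mask: np.ndarray) -> float:
    """Pore-pixel fraction of a grain mask (True = grain)."""
    grain_mask = np.asarray(grain_mask, bool)
    if grain_mask.size == 0:
        raise ValueError("empty grain mask")
    return 1.0 - float(grain_mask.mean())


def biofilm_coverage(phase_map: PhaseMap) -> float:
    """BIOFILM pixels / non-GRAIN pixels.

    The denominator is the full pore space (including gas-occupied pixels).
    """
    return phase_map.fraction(BIOFILM)


def gas_saturation(phase_map: PhaseMap) -> float:
    """GAS pixels / non-GRAIN pixels."""
    return phase_map.fraction(GAS)


def saturation_reduction(sat_before: float, sat_after: float,
                         relative: bool = True) -> float:
    """Percent reduction in gas saturation.

    ``relative=True`` (default) gives 100·(before − after)/before; set
    ``relative=False`` for percentage points (100·(before − after)).
    """
    if relative:
        if sat_before <= 0:
            raise ValueError("sat_before must be > 0 for a relative reduction")
        return 100.0 * (sat_before - sat_after) / sat_before
    return 100.0 * (sat_before - sat_after)


def normalize_series(series: CoverageSeries, reference_index: int) -> CoverageSeries:
    """Divide coverage by its value at the reference time point.

    The reference is the frame right after biofilm formation under lactate
    conditions (end of the growth phase); normalized coverage may exceed 1
    during later growth.
    """
    if not 0 <= reference_index < len(series.coverage):
        raise IndexError("reference_index outside series")
    ref = series.coverage[reference_index]
    if ref <= 0:
        raise ValueError(
            "zero coverage at reference; choose the first nonzero frame"
        )
    return CoverageSeries(
        timestamps=series.timestamps,
        coverage=series.coverage,
        condition=series.condition,
        cycle_end_indices=list(series.cycle_end_indices),
        normalized=series.coverage / ref,
        reference_index=reference_index,
    )


def cumulative_detachment(
    normalized: np.ndarray, cycle_end_indices: list[int]
) -> pd.DataFrame:
    """Per-cycle biofilm loss relative to the reference coverage.

    ``cumulative[k] = 100·(1 − normalized[end_k])`` (% of initial biofilm);
    ``incremental[k]`` is the percentage-point decrease attributable to
    cycle ``k``.
    """
    normalized = np.asarray(normalized, float)
    idx = list(cycle_end_indices)
    if idx != sorted(idx):
        raise ValueError("cycle_end_indices must be ascending")
    if any(i < 0 or i >= len(normalized) for i in idx):
        raise IndexError("cycle_end_indices outside series")
    ends = normalized[idx]
    if np.any(ends > 2.0):
        raise ValueError("normalized coverage > 2 at a cycle end; check reference")
    cumulative = 100.0 * (1.0 - ends)
    incremental = np.diff(np.concatenate([[0.0], cumulative]))
    return pd.DataFrame({
        "cycle": np.arange(1, len(idx) + 1),
        "end_index": idx,
        "cumulative_pct": cumulative,
        "incremental_pct_points": incremental,
    })


def _boundary_free_gas(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Label GAS components; split into interior ganglia vs boundary-connected."""
    gas = labels == GAS
    lab = _skmeasure.label(gas, connectivity=2)
    edge_labels = np.unique(np.concatenate([
        lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]
    ]))
    edge_labels = edge_labels[edge_labels > 0]
    interior = lab.copy()
    interior[np.isin(lab, edge_labels)] = 0
    return lab, interior


def ganglia_table(phase_maps: list[PhaseMap]) -> pd.DataFrame:
    """Trapped-gas ganglia tracked over time.

    A ganglion is a connected GAS component not touching the frame boundary
    (boundary-connected gas is flowing, not trapped).  Ganglia are linked
    across consecutive time points by maximal pixel overlap (ties to the
    larger overlap, then the lower label).  Columns: time_index, ganglion_id,
    area_px, centroid_x, centroid_y, dissolved (True on a ganglion's final
    sighting when it vanishes before the series ends).
    """
    if len(phase_maps) < 2:
        raise ValueError("need at least 2 time points")
    rows: list[dict] = []
    next_id = 1
    prev_interior = None
    prev_ids: dict[int, int] = {}
    for t, pm in enumerate(phase_maps):
        _, interior = _boundary_free_gas(pm.labels)
        ids: dict[int, int] = {}
        for p in _skmeasure.regionprops(interior):
            gid = None
            if prev_interior is not None:
                overlap_counts: dict[int, int] = {}
                prev_slice = prev_interior[tuple(p.coords.T)]
                for prev_lab in prev_slice[prev_slice > 0]:
                    overlap_counts[prev_lab] = overlap_counts.get(prev_lab, 0) + 1
                if overlap_counts:
                    best = sorted(overlap_counts.items(),
                                  key=lambda kv: (-kv[1], kv[0]))[0][0]
                    gid = prev_ids.get(best)
            if gid is None:
                gid = next_id
                next_id += 1
            ids[p.label] = gid
            rows.append({
                "time_index": t,
                "ganglion_id": gid,
                "area_px": int(p.area),
                "centroid_x": p.centroid[1],
                "centroid_y": p.centroid[0],
            })
        prev_interior, prev_ids = interior, ids
    df = pd.DataFrame(rows, columns=["time_index", "ganglion_id", "area_px",
                                     "centroid_x", "centroid_y"])
    if df.empty:
        df["dissolved"] = pd.Series(dtype=bool)
        return df
    last_t = len(phase_maps) - 1
    last_seen = df.groupby("ganglion_id")["time_index"].max()
    df["dissolved"] = df.apply(
        lambda r: bool(last_seen[r["ganglion_id"]] == r["time_index"] != last_t),
        axis=1,
    )
    return df


def ganglia_shrinkage(table: pd.DataFrame) -> pd.DataFrame:
    """Relative area change per ganglion between first and last sighting."""
    out = []
    for gid, g in table.groupby("ganglion_id"):
        g = g.sort_values("time_index")
        a0, a1 = g["area_px"].iloc[0], g["area_px"].iloc[-1]
        out.append({
            "ganglion_id": gid,
            "first_area_px": a0,
            "last_area_px": a1,
            "shrinkage_pct": 100.0 * (a0 - a1) / a0 if a0 else np.nan,
        })
    return pd.DataFrame(out)


def _gas_liquid_boundary(labels: np.ndarray) -> np.ndarray:
    """GAS pixels with a 4-neighbour LIQUID pixel (the g/l interface)."""
    gas = labels == GAS
    liquid = labels == LIQUID
    neigh = ndimage.binary_dilation(liquid, structure=ndimage.generate_binary_structure(2, 1))
    return gas & neigh


def interface_displacement(pm1: PhaseMap, pm2: PhaseMap) -> float:
    """Mean gas–liquid interface displacement between two phase maps (μm).

    For every interface pixel at t1, the distance to the nearest interface
    pixel at t2 is taken; the mean is scaled by the pixel size.
    """
    if pm1.labels.shape != pm2.labels.shape:
        raise ValueError("phase maps differ in shape")
    b1 = _gas_liquid_boundary(pm1.labels)
    b2 = _gas_liquid_boundary(pm2.labels)
    if not b1.any() or not b2.any():
        raise ValueError("a phase map lacks a gas–liquid interface")
    dist_to_b2 = ndimage.distance_transform_edt(~b2)
    return float(dist_to_b2[b1].mean()) * pm1.pixel_size_um
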