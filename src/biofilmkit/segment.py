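"""Grayscale-to-regions segmentation.

The measurement chain for every imaging system is the same: build an
intensity histogram, place multi-Otsu thresholds (k classes maximising
between-class variance), binarise, label connected components and extract
per-region geometry, then split regions into single cells versus biofilm by
area.  Cells are a few μm² in footprint; biofilms are extended dark
structures orders of magnitude larger, so a single area cutoff separates the
two robustly.

The multi-Otsu search is exhaustive (dynamic programme over all threshold
placements) with a deterministic tie rule — ties broken toward the
lexicographically smallest threshold tuple — so results are reproducible
bit-for-bit and checkable against a brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure as _skmeasure

__all__ = [
    "Histogram",
    "intensity_histogram",
    "multi_otsu_thresholds",
    "apply_thresholds",
    "label_components",
    "region_properties",
    "classify_regions",
    "remove_linear_gradient",
    "normalize_series_intensity",
    "CELL",
    "BIOFILM",
    "EXCLUDED",
]

CELL = "CELL"
BIOFILM = "BIOFILM"
EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class Histogram:
    """Equal-width intensity histogram over [0, 1].

    ``bin_edges`` has ``n + 1`` strictly increasing values; ``counts`` has
    ``n`` non-negative integers summing to the pixel count.  Bins are
    right-open except the last, which is closed (standard numpy convention).
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, float))
        object.__setattr__(self, "counts", np.asarray(self.counts))
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have len(counts)+1 entries")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def intensity_histogram(pixels: np.ndarray, n_bins: int = 256) -> Histogram:
    """Histogram pixel intensities into ``n_bins`` equal-width bins on [0, 1]."""
    pixels = np.asarray(pixels, float)
    if pixels.size == 0:
        raise ValueError("cannot histogram an empty image")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    counts, edges = np.histogram(pixels.ravel(), bins=n_bins, range=(0.0, 1.0))
    return Histogram(bin_edges=edges, counts=counts)


def _integer_counts(counts: np.ndarray) -> list[int]:
    """Histogram counts as exact integers (they are pixel counts)."""
    rounded = np.rint(counts)
    if not np.allclose(counts, rounded, atol=1e-9):
        raise ValueError("histogram counts must be integers")
    return [int(c) for c in rounded]


def multi_otsu_thresholds(hist: Histogram, n_classes: int = 3) -> np.ndarray:
    """Multi-level Otsu thresholds from a histogram.

    Performs an exhaustive search (dynamic programme over every placement of
    ``n_classes − 1`` cut points) for the partition maximising between-class
    variance.  Among tied optima the lexicographically smallest threshold
    tuple is returned.  Thresholds are intensity values at bin upper edges.

    Maximising Σ_k ω_k (μ_k − μ_T)² is equivalent to maximising the
    separable score Σ_k S_k²/W_k, with S/W a segment's sums of count·centre
    and count.  Because equal-width bin centres are proportional to odd
    integers and counts are integers, the score is evaluated in exact
    rational arithmetic — the argmax and the tie rule are never at the
    mercy of floating-point round-off.

    Raises ``ValueError`` if the histogram populates fewer bins than classes.
    """
    if n_classes not in (2, 3, 4):
        raise ValueError("n_classes must be 2, 3 or 4")
    nonempty = int(np.count_nonzero(hist.counts))
    if nonempty < n_classes:
        raise ValueError(
            f"histogram has only {nonempty} nonempty bins, "
            f"fewer than {n_classes} classes"
        )
    n = len(hist.counts)
    w = _integer_counts(hist.counts)
    # bin centre ∝ (2i + 1); the constant 1/(2n) scale drops out of the argmax
    cw = [0] * (n + 1)
    cs = [0] * (n + 1)
    for i in range(n):
        cw[i + 1] = cw[i] + w[i]
        cs[i + 1] = cs[i] + w[i] * (2 * i + 1)

    def seg(a: int, b: int) -> tuple[int, int]:
        """Exact S²/W of bins [a, b) as a (num, den) pair; 0 when empty."""
        ww = cw[b] - cw[a]
        if ww == 0:
            return 0, 1
        s = cs[b] - cs[a]
        return s * s, ww

    def r_add(x: tuple[int, int], y: tuple[int, int]) -> tuple[int, int]:
        return x[0] * y[1] + y[0] * x[1], x[1] * y[1]

    def r_gt(x: tuple[int, int], y: tuple[int, int]) -> bool:
        return x[0] * y[1] > y[0] * x[1]

    def r_eq(x: tuple[int, int], y: tuple[int, int]) -> bool:
        return x[0] * y[1] == y[0] * x[1]

    # best[k][a]: max score splitting bins [a, n) into k classes
    best: list[list[tuple[int, int] | None]] = [
        [None] * (n + 1) for _ in range(n_classes + 1)
    ]
    best[1] = [seg(a, n) for a in range(n + 1)]
    for k in range(2, n_classes + 1):
        hi = n - k + 1  # last cut position so every later class can be placed
        for a in range(n + 1):
            if a >= hi:
                continue
            acc = None
            for c in range(a + 1, hi + 1):
                cand = r_add(seg(a, c), best[k - 1][c])
                if acc is None or r_gt(cand, acc):
                    acc = cand
            best[k][a] = acc

    # greedy reconstruction: smallest cut achieving the optimum at each level
    cuts: list[int] = []
    a = 0
    for k in range(n_classes, 1, -1):
        target = best[k][a]
        for c in range(a + 1, n - k + 2):
            if r_eq(r_add(seg(a, c), best[k - 1][c]), target):
                cuts.append(c)
                a = c
                break
    # cut c splits after bin c-1 → threshold is bin (c-1)'s upper edge
    return np.array([hist.bin_edges[c] for c in cuts])


def apply_thresholds(
    pixels: np.ndarray,
    thresholds: np.ndarray,
    foreground_classes: set[int] | frozenset[int],
) -> np.ndarray:
    """Binary mask of pixels whose intensity class is in ``foreground_classes``.

    Class ``k`` means ``t_{k-1} < I <= t_k`` with sentinel thresholds at ±∞;
    class indices start at 0 (darkest band).
    """
    thresholds = np.asarray(thresholds, float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    classes = np.searchsorted(thresholds, np.asarray(pixels, float), side="left")
    mask = np.zeros_like(classes, dtype=bool)
    for k in foreground_classes:
        mask |= classes == k
    return mask


def label_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label maximal connected foreground components 1..K.

    ``connectivity`` is 4 (edge neighbours) or 8 (edge + corner).  Labels are
    assigned in raster-scan order of each component's first pixel; background
    stays 0.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab = _skmeasure.label(np.asarray(mask, bool), connectivity=1 if connectivity == 4 else 2)
    return _relabel_raster_order(lab)


def _relabel_raster_order(lab: np.ndarray) -> np.ndarray:
    """Renumber labels by first raster-scan appearance (determinism contract)."""
    flat = lab.ravel()
    fg = flat[flat > 0]
    if fg.size == 0:
        return lab
    first = {}
    order = []
    for v in fg:
        if v not in first:
            first[v] = len(order) + 1
            order.append(v)
    remap = np.zeros(int(lab.max()) + 1, dtype=lab.dtype)
    for old, new in first.items():
        remap[old] = new
    return remap[lab]


def region_properties(label_map: np.ndarray, pixel_size_um: float) -> pd.DataFrame:
    """Per-region geometry table.

    Columns: ``label``, ``area_px``, ``area_um2`` (= area_px·pixel_size²),
    ``centroid_x``/``centroid_y`` (unweighted pixel-coordinate means),
    ``bbox_x0/y0/x1/y1`` (half-open).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    props = _skmeasure.regionprops(label_map)
    rows = []
    for p in props:
        (y0, x0, y1, x1) = p.bbox
        rows.append(
            {
                "label": p.label,
                "area_px": int(p.area),
                "area_um2": float(p.area) * pixel_size_um**2,
                "centroid_x": p.centroid[1],
                "centroid_y": p.centroid[0],
                "bbox_x0": x0,
                "bbox_y0": y0,
                "bbox_x1": x1,
                "bbox_y1": y1,
            }
        )
    cols = [
        "label", "area_px", "area_um2", "centroid_x", "centroid_y",
        "bbox_x0", "bbox_y0", "bbox_x1", "bbox_y1",
    ]
    return pd.DataFrame(rows, columns=cols)


def classify_regions(
    table: pd.DataFrame,
    cell_area_max_um2: float = 50.0,
    min_area_um2: float = 0.0,
) -> pd.DataFrame:
    """Split regions into single cells versus biofilm by area.

    ``area_um2 <= cell_area_max_um2`` → CELL (inclusive boundary), larger →
    BIOFILM; regions below ``min_area_um2`` are EXCLUDED (noise specks).  The
    default 50 μm² cutoff is a few footprints of a ~1×3 μm vibrioid cell
    and is a config key, not a measured constant.
    """
    if cell_area_max_um2 <= 0:
        raise ValueError("cell_area_max_um2 must be > 0")
    out = table.copy()
    cls = np.where(out["area_um2"] <= cell_area_max_um2, CELL, BIOFILM)
    cls = np.where(out["area_um2"] < min_area_um2, EXCLUDED, cls)
    out["region_class"] = cls
    return out


def remove_linear_gradient(pixels: np.ndarray) -> np.ndarray:
    """Subtract a least-squares plane fit (linear illumination gradient).

    The mean intensity is preserved and the result re-clipped to [0, 1].
    """
    pixels = np.asarray(pixels, float)
    h, w = pixels.shape
    yy, xx = np.mgrid[0:h, 0:w]
    a = np.column_stack([xx.ravel(), yy.ravel(), np.ones(pixels.size)])
    coef, *_ = np.linalg.lstsq(a, pixels.ravel(), rcond=None)
    plane = (a @ coef).reshape(h, w)
    return np.clip(pixels - plane + plane.mean(), 0.0, 1.0)


def normalize_series_intensity(frames: np.ndarray) -> np.ndarray:
    """Min–max normalise a whole acquisition series to [0, 1].

    Normalisation is per series, not per frame, so thresholds remain
    comparable over time.
    """
    frames = np.asarray(frames, float)
    lo, hi = frames.min(), frames.max()
    if hi == lo:
        raise ValueError("constant series cannot be normalised")
    return (frames - lo) / (hi - lo)
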