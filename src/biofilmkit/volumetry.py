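"""3D biofilm reconstruction and quantification from segmented Z-slices.

Segmented binary slices are stacked along Z into an anisotropic voxel
volume (XY pixel size ≠ Z step), connected components are labeled in 3D,
small non-biofilm debris is filtered out, and a triangulated isosurface is
extracted with marching cubes.  Biofilm amount is quantified two ways —
voxel count × voxel volume, and mesh-enclosed volume by the divergence
theorem — which converge as structures grow large against the voxel size.
Time series of biofilm quantity are expressed as percent change relative
to the initial frame, and individual biofilms are followed over time by
greedy nearest-centroid linking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure as _skmeasure

__all__ = [
    "BinaryVolume",
    "SurfaceMesh",
    "stack_slices",
    "label_volume",
    "filter_volume_regions",
    "extract_surface",
    "mesh_measures",
    "relative_change_series",
    "track_biofilm_positions",
    "write_stl",
    "write_obj",
]


@dataclass
class BinaryVolume:
    """(Z, Y, X) boolean voxel volume with physical calibration."""

    voxels: np.ndarray
    pixel_size_um: float
    z_step_um: float
    z0_um: float = 0.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, bool)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3D (Z, Y, X)")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("calibration must be positive")

    @property
    def anisotropy(self) -> float:
        return self.z_step_um / self.pixel_size_um

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_size_um**2 * self.z_step_um

    @property
    def depth_um(self) -> float:
        """Physical Z extent spanned by the slice planes."""
        return (self.voxels.shape[0] - 1) * self.z_step_um


@dataclass
class SurfaceMesh:
    """Triangle mesh in micrometre coordinates (x, y, z)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, int).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edge_face_counts(self) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for tri in self.faces:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (min(a, b), max(a, b))
                counts[key] = counts.get(key, 0) + 1
        return counts

    def is_watertight(self) -> bool:
        """Closed surface: every edge shared by an even number of faces.

        Binary fields contoured at 0.5 can produce non-manifold edges (four
        incident faces) where two voxel bodies touch along a voxel edge;
        such meshes still bound a volume, so closedness — no boundary edge
        with an odd face count — is the operative criterion for the volume
        and area integrals.
        """
        if self.n_faces == 0:
            return True
        return all(c % 2 == 0 for c in self.edge_face_counts().values())

    def is_manifold(self) -> bool:
        """Strictly manifold: every edge shared by exactly two faces."""
        if self.n_faces == 0:
            return True
        return all(c == 2 for c in self.edge_face_counts().values())


def stack_slices(
    slices: list[np.ndarray],
    pixel_size_um: float,
    z_step_um: float,
    z0_um: float = 0.0,
) -> BinaryVolume:
    """Stack segmented binary 2D slices sequentially along the Z-axis.

    Voxel (k, y, x) takes slice k's pixel (y, x); the physical Z coordinate
    of slice k is ``z0 + k·z_step``.  Raises on a shape mismatch, naming the
    offending slice.
    """
    if len(slices) < 2:
        raise ValueError("need at least 2 slices")
    shape0 = np.asarray(slices[0]).shape
    for k, s in enumerate(slices):
        if np.asarray(s).shape != shape0:
            raise ValueError(f"slice {k} has shape {np.asarray(s).shape}, expected {shape0}")
    vox = np.stack([np.asarray(s, bool) for s in slices], axis=0)
    return BinaryVolume(vox, pixel_size_um, z_step_um, z0_um)


def label_volume(volume: BinaryVolume) -> tuple[np.ndarray, pd.DataFrame]:
    """26-connected component labeling of a binary volume.

    Returns the labeled (Z, Y, X) array and a table (label, voxel_count,
    volume_um3, centroid_x/y/z in voxel units).  Voxel counts are conserved:
    their sum equals the true-voxel count.
    """
    lab = _skmeasure.label(volume.voxels, connectivity=3)
    rows = []
    for p in _skmeasure.regionprops(lab):
        cz, cy, cx = p.centroid
        rows.append({
            "label": p.label,
            "voxel_count": int(p.area),
            "volume_um3": float(p.area) * volume.voxel_volume_um3,
            "centroid_x": cx,
            "centroid_y": cy,
            "centroid_z": cz,
        })
    cols = ["label", "voxel_count", "volume_um3",
            "centroid_x", "centroid_y", "centroid_z"]
    return lab, pd.DataFrame(rows, columns=cols)


def filter_volume_regions(
    labeled: np.ndarray, min_voxels: int = 1
) -> np.ndarray:
    """Drop components below ``min_voxels``; compact the surviving labels.

    This is the "exclude single cells and irrelevant structures" step:
    isolated cells are a voxel or two, biofilms are orders of magnitude
    larger.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    labels, counts = np.unique(labeled[labeled > 0], return_counts=True)
    keep = labels[counts >= min_voxels]
    remap = np.zeros(int(labeled.max()) + 1, labeled.dtype)
    for new, old in enumerate(sorted(keep), start=1):
        remap[old] = new
    return remap[labeled]


def extract_surface(volume: BinaryVolume, iso_level: float = 0.5) -> SurfaceMesh:
    """Marching-cubes isosurface of a binary volume, in micrometres.

    The volume is padded with one empty voxel layer so all surfaces close.
    The binary field (0/1 at voxel centres) is contoured at ``iso_level``;
    with the default 0.5, crossings sit at cell-edge midpoints.  Vertices
    are scaled by (pixel_size, pixel_size, z_step) after extraction and
    returned in (x, y, z) order; faces are consistently outward-oriented.
    Ambiguous cube faces are resolved by the standard case table — rare for
    binary fields at iso 0.5 and accepted as a known approximation.
    """
    if not 0.0 < iso_level < 1.0:
        raise ValueError("iso_level must be in (0, 1)")
    if not volume.voxels.any():
        return SurfaceMesh(np.empty((0, 3)), np.empty((0, 3), int))
    padded = np.pad(volume.voxels, 1, mode="constant").astype(float)
    verts, faces, _, _ = _skmeasure.marching_cubes(
        padded, level=iso_level,
        spacing=(volume.z_step_um, volume.pixel_size_um, volume.pixel_size_um),
    )
    # skimage returns (z, y, x) vertex coordinates; reorder to (x, y, z) and
    # flip a face index pair to keep outward orientation under the swap.
    verts_xyz = verts[:, ::-1]
    faces = faces[:, [0, 2, 1]]
    return SurfaceMesh(verts_xyz, faces)


def mesh_measures(mesh: SurfaceMesh) -> tuple[float, float]:
    """(enclosed_volume_um3, surface_area_um2) of a watertight mesh.

    Volume by the signed-tetrahedron (divergence theorem) sum, reported as
    an absolute value so face orientation cannot flip the sign; area as the
    sum of triangle areas.  Raises on a non-watertight mesh, reporting the
    number of offending edges.
    """
    if mesh.n_faces == 0:
        return 0.0, 0.0
    bad = sum(1 for c in mesh.edge_face_counts().values() if c % 2 != 0)
    if bad:
        raise ValueError(
            f"mesh is not watertight: {bad} edges with an odd face count")
    tri = mesh.vertices[mesh.faces]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    signed = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    volume = abs(float(signed.sum()))
    area = float(np.linalg.norm(np.cross(b - a, c - a), axis=1).sum() / 2.0)
    return volume, area


def relative_change_series(
    values: np.ndarray, reference_index: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Percent change of a series versus a reference point.

    Returns ``(percent_change, ratio)`` where
    ``percent_change[t] = 100·(v[t] − v[ref])/v[ref]`` and
    ``ratio[t] = v[t]/v[ref]``.  Raises when the reference value is zero
    (choose the first nonzero frame instead).
    """
    values = np.asarray(values, float)
    ref = values[reference_index]
    if ref <= 0:
        nz = np.flatnonzero(values > 0)
        hint = f"; first nonzero frame is {nz[0]}" if nz.size else ""
        raise ValueError(f"reference value is not positive{hint}")
    ratio = values / ref
    return 100.0 * (ratio - 1.0), ratio


def track_biofilm_positions(
    region_tables: list[pd.DataFrame],
    max_disp_um: float,
    pixel_size_um: float,
) -> pd.DataFrame:
    """Follow individual biofilm regions across time points.

    Greedy nearest-centroid linking: at each step the closest
    (track, region) pair within ``max_disp_um`` is linked first; unmatched
    regions start new tracks; a track with no match simply ends.  Columns:
    track_id, time_index, label, centroid_x, centroid_y, area_px.
    """
    if len(region_tables) < 2:
        raise ValueError("need at least 2 time points")
    rows: list[dict] = []
    next_id = 1
    live: dict[int, tuple[float, float]] = {}
    for t, table in enumerate(region_tables):
        cents = [(r["centroid_x"], r["centroid_y"]) for _, r in table.iterrows()]
        assigned: dict[int, int] = {}
        if live and cents:
            pairs = sorted(
                (np.hypot(cx - lx, cy - ly) * pixel_size_um, tid, ri)
                for tid, (lx, ly) in live.items()
                for ri, (cx, cy) in enumerate(cents)
            )
            used_t, used_r = set(), set()
            for d, tid, ri in pairs:
                if d > max_disp_um:
                    break
                if tid in used_t or ri in used_r:
                    continue
                assigned[ri] = tid
                used_t.add(tid)
                used_r.add(ri)
        new_live: dict[int, tuple[float, float]] = {}
        for ri, (_, r) in enumerate(table.iterrows()):
            tid = assigned.get(ri)
            if tid is None:
                tid = next_id
                next_id += 1
            new_live[tid] = (r["centroid_x"], r["centroid_y"])
            rows.append({
                "track_id": tid,
                "time_index": t,
                "label": r["label"],
                "centroid_x": r["centroid_x"],
                "centroid_y": r["centroid_y"],
                "area_px": r["area_px"],
            })
        live = new_live
    return pd.DataFrame(rows, columns=["track_id", "time_index", "label",
                                       "centroid_x", "centroid_y", "area_px"])


def write_stl(mesh: SurfaceMesh, path: str | Path, name: str = "biofilm") -> Path:
    """Write an ASCII STL file."""
    path = Path(path)
    tri = mesh.vertices[mesh.faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    lens = np.linalg.norm(normals, axis=1)
    lens[lens == 0] = 1.0
    normals = normals / lens[:, None]
    lines = [f"solid {name}"]
    for n, t in zip(normals, tri):
        lines.append(f"  facet normal {n[0]:.6e} {n[1]:.6e} {n[2]:.6e}")
        lines.append("    outer loop")
        for v in t:
            lines.append(f"      vertex {v[0]:.6e} {v[1]:.6e} {v[2]:.6e}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append(f"endsolid {name}\n")
    path.write_text("\n".join(lines))
    return path


def write_obj(mesh: SurfaceMesh, path: str | Path) -> Path:
    """Write a Wavefront OBJ file (1-based face indices)."""
    path = Path(path)
    lines = [f"v {v[0]:.6e} {v[1]:.6e} {v[2]:.6e}" for v in mesh.vertices]
    lines += [f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}" for f in mesh.faces]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_obj(path: str | Path) -> SurfaceMesh:
    """Read a mesh written by :func:`write_obj`."""
    verts, faces = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(p) for p in parts[1:4]])
        elif parts[0] == "f":
            faces.append([int(p) - 1 for p in parts[1:4]])
    return SurfaceMesh(np.array(verts).reshape(-1, 3),
                       np.array(faces, int).reshape(-1, 3))
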