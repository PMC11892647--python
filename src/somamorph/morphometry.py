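"""Per-cell morphometry: volumes, surface distances, depth/side/face labels.

The measurement chain mirrors how annotated somata are quantified from a
segmented ganglion volume: fine neuritic processes are stripped by
morphological opening, each soma is meshed, its minimum distance to the
smoothed ganglionic surface is found by nearest-neighbor search, and the
population is split into superficial (distance < tau) and internalized
(distance >= tau) classes, with side and face assigned from the centroid
and the local surface normal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree

from .meshing import SurfaceModel, _mesh_from_binary, mesh_volume
from .phantom import LabelVolume

__all__ = [
    "MorphConfig",
    "CellRecord",
    "remove_fine_processes",
    "filter_small_somata",
    "min_surface_distance",
    "classify_depth",
    "assign_side_and_face",
    "measure_all",
    "records_to_frame",
    "equivalent_sphere_diameter",
]

log = logging.getLogger("somamorph")

DistanceMode = Literal["vertex_to_vertex", "point_to_triangle"]


@dataclass(frozen=True)
class MorphConfig:
    """Measurement parameters.

    ``superficial_threshold_um`` is the surface-distance cut tau: strictly
    below it a soma is superficial, at or above it internalized.
    ``min_soma_diameter_um`` flags (not deletes) cells whose
    equivalent-sphere diameter is not strictly above the soma criterion.
    The midsagittal plane defaults to the x-midplane of the volume.
    """

    superficial_threshold_um: float = 8.125
    min_soma_diameter_um: float = 8.0
    min_process_diameter_um: float = 2.5
    distance_mode: DistanceMode = "vertex_to_vertex"
    midsagittal_point_um: Optional[tuple[float, float, float]] = None
    midsagittal_normal: tuple[float, float, float] = (1.0, 0.0, 0.0)
    dorsoventral_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    face_other_band: float = 0.3
    # face normals are averaged over surface vertices within
    # (distance + face_patch_scale * equivalent radius) of the centroid,
    # so a soma's own surface bump does not dominate its normal
    face_patch_scale: float = 7.0

    def __post_init__(self) -> None:
        if self.superficial_threshold_um <= 0:
            raise ValueError("superficial_threshold_um must be positive")
        if self.min_soma_diameter_um <= 0 or self.min_process_diameter_um <= 0:
            raise ValueError("diameters must be positive")
        for name in ("midsagittal_normal", "dorsoventral_axis"):
            v = np.asarray(getattr(self, name), float)
            if not math.isclose(float(np.linalg.norm(v)), 1.0, rel_tol=1e-6):
                raise ValueError(f"{name} must be unit-norm")


@dataclass
class CellRecord:
    """One measured soma."""

    cell_id: int
    side: str = "right"
    face: str = "none"
    volume_mesh_um3: float = float("nan")
    volume_voxel_um3: float = float("nan")
    centroid_um: tuple[float, float, float] = (float("nan"),) * 3
    surface_distance_um: float = float("nan")
    depth_class: str = "internalized"
    included: bool = True


_RECORD_COLUMNS = [
    "cell_id",
    "side",
    "face",
    "volume_mesh_um3",
    "volume_voxel_um3",
    "cx_um",
    "cy_um",
    "cz_um",
    "surface_distance_um",
    "depth_class",
    "included",
]


def records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Fixed-column-order DataFrame view of measured records."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "side": [r.side for r in records],
            "face": [r.face for r in records],
            "volume_mesh_um3": [r.volume_mesh_um3 for r in records],
            "volume_voxel_um3": [r.volume_voxel_um3 for r in records],
            "cx_um": [r.centroid_um[0] for r in records],
            "cy_um": [r.centroid_um[1] for r in records],
            "cz_um": [r.centroid_um[2] for r in records],
            "surface_distance_um": [r.surface_distance_um for r in records],
            "depth_class": [r.depth_class for r in records],
            "included": [r.included for r in records],
        },
        columns=_RECORD_COLUMNS,
    )


def equivalent_sphere_diameter(volume_um3: float) -> float:
    """Diameter of the sphere with the given volume."""
    return 2.0 * (3.0 * volume_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# mask cleanup
# ---------------------------------------------------------------------------

def remove_fine_processes(
    cell_mask: np.ndarray, spacing_um, min_process_diameter_um: float = 2.5
) -> np.ndarray:
    """Strip neuritic processes thinner than the process criterion.

    Morphological opening with a Euclidean ball of radius
    ``min_process_diameter_um / 2`` (metric distance transforms, so voxel
    anisotropy is respected), then retention of the largest 26-connected
    component — the soma. Output is a subset of the input.
    """
    mask = np.asarray(cell_mask, bool)
    if not mask.any():
        raise ValueError("cell mask is empty")
    sp = np.asarray(spacing_um, float)
    r = min_process_diameter_um / 2.0
    if r < sp.min() / 2.0:
        opened = mask  # structuring element below voxel scale: opening is identity
    else:
        d_in = ndimage.distance_transform_edt(mask, sampling=sp)
        eroded = d_in > r
        if not eroded.any():
            raise ValueError(
                "opening erased the cell entirely: structure thinner than "
                f"{min_process_diameter_um} µm everywhere (fine process, not a soma)"
            )
        d_out = ndimage.distance_transform_edt(~eroded, sampling=sp)
        opened = mask & (d_out <= r)
    lab, n = ndimage.label(opened, structure=np.ones((3, 3, 3), bool))
    if n > 1:
        sizes = ndimage.sum_labels(opened, lab, index=np.arange(1, n + 1))
        opened = lab == (int(np.argmax(sizes)) + 1)
    return opened


def filter_small_somata(
    records: Sequence[CellRecord], min_soma_diameter_um: float = 8.0
) -> list[CellRecord]:
    """Flag cells failing the strict soma-size criterion (diameter > min).

    The equivalent-sphere diameter is computed from the voxel-count
    volume; the boundary is exclusive, so a cell at exactly the minimum
    diameter is excluded. The list length is unchanged (flagging, not
    deletion).
    """
    out = []
    for r in records:
        d_eq = equivalent_sphere_diameter(r.volume_voxel_um3)
        out.append(replace_included(r, r.included and d_eq > min_soma_diameter_um))
    return out


def replace_included(record: CellRecord, included: bool) -> CellRecord:
    rec = CellRecord(**vars(record))
    rec.included = bool(included)
    return rec


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _point_triangle_distances(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distances from each point to its paired triangle.

    ``points``: (n, 3); ``tri``: (n, 3, 3). Region-based closest-point
    computation on the triangle's barycentric parameterization.
    """
    b, e0, e1 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    d = b - points
    a = np.einsum("ij,ij->i", e0, e0)
    bb = np.einsum("ij,ij->i", e0, e1)
    c = np.einsum("ij,ij->i", e1, e1)
    dd = np.einsum("ij,ij->i", e0, d)
    e = np.einsum("ij,ij->i", e1, d)
    det = np.maximum(a * c - bb * bb, 1e-300)
    s = np.clip((bb * e - c * dd) / det, 0.0, 1.0)
    t = np.clip((bb * dd - a * e) / det, 0.0, 1.0)
    # clamp into the triangle s + t <= 1 by re-projecting onto each edge
    # and keeping the best candidate (simple and robust, if not minimal)
    cand = []
    for ss, tt in ((s, t),):
        over = ss + tt > 1.0
        ss2, tt2 = ss.copy(), tt.copy()
        ss2[over] = np.clip(ss[over] + (1 - ss[over] - tt[over]) / 2, 0, 1)
        tt2[over] = 1 - ss2[over]
        cand.append((ss2, tt2))
    # edge candidates: t=0, s=0, s+t=1
    s0 = np.clip(-dd / np.maximum(a, 1e-300), 0.0, 1.0)
    cand.append((s0, np.zeros_like(s0)))
    t0 = np.clip(-e / np.maximum(c, 1e-300), 0.0, 1.0)
    cand.append((np.zeros_like(t0), t0))
    shyp = np.clip((c + e - bb - dd) / np.maximum(a - 2 * bb + c, 1e-300), 0.0, 1.0)
    cand.append((shyp, 1.0 - shyp))
    best = np.full(len(points), np.inf)
    for ss, tt in cand:
        p = b + ss[:, None] * e0 + tt[:, None] * e1
        dist = np.linalg.norm(p - points, axis=1)
        best = np.minimum(best, dist)
    return best


def min_surface_distance(
    cell: trimesh.Trimesh,
    surface: SurfaceModel | trimesh.Trimesh,
    mode: DistanceMode = "vertex_to_vertex",
    surface_tree: Optional[cKDTree] = None,
) -> float:
    """Minimum distance (µm) from a cell mesh to the ganglionic surface.

    ``vertex_to_vertex``: nearest-neighbor search between the cell's
    vertices and the surface's vertices (equals exhaustive search).
    ``point_to_triangle``: exact point-to-triangle distance from each
    cell vertex to the surface, a strictly tighter measure on coarse
    meshes. ``surface_tree`` lets callers reuse a prebuilt KD-tree.
    """
    smesh = surface.mesh if isinstance(surface, SurfaceModel) else surface
    pts = np.asarray(cell.vertices, float)
    sverts = np.asarray(smesh.vertices, float)
    if len(pts) == 0 or len(sverts) == 0:
        raise ValueError("empty vertex set")
    tree = surface_tree if surface_tree is not None else cKDTree(sverts)
    d_vv, nearest = tree.query(pts)
    if mode == "vertex_to_vertex":
        return float(d_vv.min())
    if mode != "point_to_triangle":
        raise ValueError(f"unknown distance mode: {mode!r}")
    tris = np.asarray(smesh.triangles, float)
    centroids = tris.mean(axis=1)
    tri_radius = float(np.linalg.norm(tris - centroids[:, None, :], axis=2).max())
    ctree = cKDTree(centroids)
    upper = float(d_vv.min())  # vertex distance bounds the true distance above
    best = upper
    for p in pts:
        cand = ctree.query_ball_point(p, best + tri_radius + 1e-12)
        if not cand:
            continue
        dmin = _point_triangle_distances(
            np.repeat(p[None, :], len(cand), axis=0), tris[cand]
        ).min()
        best = min(best, float(dmin))
    return best


def classify_depth(distance_um: float, tau_um: float = 8.125) -> str:
    """Superficial iff strictly closer than tau to the ganglionic surface."""
    if distance_um < 0:
        raise ValueError("distance must be non-negative")
    return "superficial" if distance_um < tau_um else "internalized"


def assign_side_and_face(
    centroid_um,
    depth_class: str,
    config: MorphConfig,
    surface: SurfaceModel | trimesh.Trimesh,
    patch_radius_um: float = 0.0,
    plane_point_um=None,
) -> tuple[str, str]:
    """Side from the midsagittal plane; face from the local surface normal.

    Side is the sign of the signed distance of the centroid to the
    midsagittal plane (+normal side = right). Superficial cells get
    dorsal/ventral from the dot product of the patch-averaged outward
    surface normal near the soma with the dorsoventral axis (magnitudes
    below ``face_other_band`` → "other"); internalized cells have no
    face. ``patch_radius_um`` sets the averaging patch (0 = single
    nearest vertex).
    """
    smesh = surface.mesh if isinstance(surface, SurfaceModel) else surface
    c = np.asarray(centroid_um, float)
    p0 = config.midsagittal_point_um if config.midsagittal_point_um is not None else plane_point_um
    if p0 is None:
        raise ValueError("no midsagittal plane point available")
    n = np.asarray(config.midsagittal_normal, float)
    side = "right" if float(np.dot(c - np.asarray(p0, float), n)) > 0 else "left"
    if depth_class == "internalized":
        return side, "none"
    tree = cKDTree(np.asarray(smesh.vertices, float))
    dist, _ = tree.query(c)
    normal = _patch_normal(
        tree, np.asarray(smesh.vertex_normals, float), c, float(dist), patch_radius_um
    )
    face = _face_from_normal(normal, config)
    return side, face


def _patch_normal(
    tree: cKDTree, vertex_normals: np.ndarray, centroid: np.ndarray,
    reach_um: float, patch_radius_um: float,
) -> np.ndarray:
    """Outward normal of the surface patch nearest a soma.

    A superficial soma forms its own bump on the operational surface, so
    a single-vertex normal reflects bump curvature, not the ganglion
    face. The macroscopic orientation is recovered by a total-least-
    squares plane fit over a cell-sized patch (smallest principal axis
    of the patch vertex scatter), sign-aligned with the mean vertex
    normal; small patches fall back to the averaged vertex normal.
    """
    idx = tree.query_ball_point(centroid, reach_um + patch_radius_um)
    if not idx:
        _, k = tree.query(centroid)
        idx = [int(k)]
    mean_normal = vertex_normals[idx].mean(axis=0)
    if len(idx) >= 8:
        pts = tree.data[idx]
        centered = pts - pts.mean(axis=0)
        _, vecs = np.linalg.eigh(centered.T @ centered)
        nv = vecs[:, 0]
        if np.dot(nv, mean_normal) < 0:
            nv = -nv
        return nv
    norm = np.linalg.norm(mean_normal)
    if norm == 0:
        _, k = tree.query(centroid)
        return vertex_normals[int(k)]
    return mean_normal / norm


def _face_from_normal(normal: np.ndarray, config: MorphConfig) -> str:
    dot = float(np.dot(normal, np.asarray(config.dorsoventral_axis, float)))
    if dot > config.face_other_band:
        return "dorsal"
    if dot < -config.face_other_band:
        return "ventral"
    return "other"


# ---------------------------------------------------------------------------
# full measurement pass
# ---------------------------------------------------------------------------

def measure_all(
    volume: LabelVolume,
    surface: SurfaceModel,
    config: Optional[MorphConfig] = None,
) -> list[CellRecord]:
    """Measure every labeled cell in the volume.

    Per label: strip fine processes → mesh → mesh/voxel volumes and
    centroid → minimum surface distance → depth class → side and face →
    soma-size inclusion flag. Deterministic given its inputs; one record
    per label, in ascending label order.
    """
    if config is None:
        config = MorphConfig()
    sp = np.asarray(volume.spacing_um, float)
    voxvol = volume.voxel_volume_um3
    plane_point = np.asarray(volume.labels.shape, float) * sp / 2.0

    smesh = surface.mesh
    tree = cKDTree(np.asarray(smesh.vertices, float))
    vertex_normals = np.asarray(smesh.vertex_normals, float)
    dv = np.asarray(config.dorsoventral_axis, float)
    ms_n = np.asarray(config.midsagittal_normal, float)
    p0 = (
        np.asarray(config.midsagittal_point_um, float)
        if config.midsagittal_point_um is not None
        else plane_point
    )

    max_label = int(volume.labels.max())
    slices = ndimage.find_objects(volume.labels)
    records: list[CellRecord] = []
    for cell_id in range(1, max_label + 1):
        sl = slices[cell_id - 1]
        if sl is None:
            continue
        crop = volume.labels[sl] == cell_id
        origin = np.array([s.start for s in sl])
        try:
            soma = remove_fine_processes(crop, sp, config.min_process_diameter_um)
        except ValueError:
            log.warning("cell=%d entirely_fine_process excluded=1", cell_id)
            records.append(CellRecord(cell_id=cell_id, included=False))
            continue
        nvox = int(soma.sum())
        idx = np.argwhere(soma)
        centroid = (idx.mean(axis=0) + origin + 0.5) * sp
        mesh = _mesh_from_binary(soma, sp, origin)
        v_mesh = mesh_volume(mesh)
        d_vv, nearest = tree.query(np.asarray(mesh.vertices, float))
        k = int(np.argmin(d_vv))
        dist = float(d_vv[k])
        if config.distance_mode == "point_to_triangle":
            dist = min_surface_distance(mesh, surface, "point_to_triangle", surface_tree=tree)
        depth_class = classify_depth(dist, config.superficial_threshold_um)
        side = "right" if float(np.dot(centroid - p0, ms_n)) > 0 else "left"
        if depth_class == "internalized":
            face = "none"
        else:
            r_eq = equivalent_sphere_diameter(nvox * voxvol) / 2.0
            c_dist = float(np.linalg.norm(centroid - np.asarray(smesh.vertices[nearest[k]], float)))
            normal = _patch_normal(
                tree, vertex_normals, centroid, c_dist, config.face_patch_scale * r_eq
            )
            face = _face_from_normal(normal, config)
        records.append(
            CellRecord(
                cell_id=cell_id,
                side=side,
                face=face,
                volume_mesh_um3=v_mesh,
                volume_voxel_um3=nvox * voxvol,
                centroid_um=tuple(float(x) for x in centroid),
                surface_distance_um=dist,
                depth_class=depth_class,
                included=True,
            )
        )
    return filter_small_somata(records, config.min_soma_diameter_um)
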