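"""Surface extraction and mesh-based volumetry for label volumes.

Triangle meshes are ``trimesh.Trimesh`` objects with vertices in physical
micrometre coordinates under the voxel-center convention (voxel index i
sits at (i + 0.5) * spacing). Marching cubes runs on a one-voxel
zero-padded crop so components touching the grid border still close, and
face winding is flipped to outward orientation (positive signed volume).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import trimesh
import trimesh.smoothing
from scipy import ndimage
from skimage.measure import marching_cubes

from .phantom import LabelVolume

__all__ = [
    "SurfaceModel",
    "cell_mesh",
    "binary_mesh",
    "derive_ganglion_mask",
    "ganglion_surface",
    "taubin_smooth",
    "mesh_volume",
    "mesh_open_edge_count",
    "voxel_volume",
]

log = logging.getLogger("somamorph")

_CONN26 = np.ones((3, 3, 3), bool)


@dataclass
class SurfaceModel:
    """Smoothed ganglionic surface mesh plus its provenance."""

    mesh: trimesh.Trimesh
    source_mask_hash: str
    smoothing_params: dict


def _mesh_from_binary(
    mask: np.ndarray, spacing: np.ndarray, origin_index: np.ndarray
) -> trimesh.Trimesh:
    """Marching cubes at level 0.5 on a zero-padded binary crop."""
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    # padded index j maps to global index j + origin - 1; voxel centers at +0.5
    verts = verts + (origin_index - 1 + 0.5) * spacing
    faces = faces[:, ::-1]  # outward winding (positive divergence-theorem volume)
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def binary_mesh(mask: np.ndarray, spacing_um) -> trimesh.Trimesh:
    """Triangle mesh of an arbitrary binary mask, in µm coordinates."""
    if not np.any(mask):
        raise ValueError("mask is empty")
    sp = np.asarray(spacing_um, float)
    return _mesh_from_binary(np.asarray(mask, bool), sp, np.zeros(3, int))


def cell_mesh(volume: LabelVolume, cell_id: int) -> trimesh.Trimesh:
    """Isosurface mesh of one labeled cell.

    The cell's binary indicator is cropped to its bounding box, padded by
    one background voxel, and meshed at level 0.5 — so the result is
    watertight and independent of all other labels in the volume.
    """
    objs = ndimage.find_objects((volume.labels == cell_id).astype(np.int8))
    if not objs or objs[0] is None:
        avail = volume.label_ids()
        head = ", ".join(map(str, avail[:20]))
        more = "..." if len(avail) > 20 else ""
        raise KeyError(f"label {cell_id} not in volume (available: {head}{more})")
    sl = objs[0]
    crop = volume.labels[sl] == cell_id
    origin = np.array([s.start for s in sl])
    return _mesh_from_binary(crop, np.asarray(volume.spacing_um, float), origin)


def derive_ganglion_mask(
    volume: LabelVolume, closing_radius_um: float = 32.5
) -> np.ndarray:
    """Solid ganglion mask from the union of all labeled cell voxels.

    The boundary of the ganglion is operationalized as the morphological
    closing (Euclidean ball of ``closing_radius_um``, anisotropy handled
    via metric distance transforms) of the cell-voxel union, followed by a
    fill of fully enclosed cavities. If the closed mask is not a single
    26-connected component, the largest component is returned and a
    warning is logged.
    """
    cells = volume.labels > 0
    if not cells.any():
        raise ValueError("volume contains no labeled cells")
    sp = np.asarray(volume.spacing_um, float)
    r = float(closing_radius_um)
    # closing = erosion(dilation): both via metric EDTs so the structuring
    # element is a true Euclidean ball even for anisotropic voxels
    d_bg = ndimage.distance_transform_edt(~cells, sampling=sp)
    dilated = d_bg <= r
    # fill before eroding: the dilated shell is where enclosure is most
    # likely complete, and erosion of the filled solid only moves the
    # outer boundary back inward
    dilated = ndimage.binary_fill_holes(dilated)
    d_in = ndimage.distance_transform_edt(dilated, sampling=sp)
    closed = d_in > r
    closed |= cells  # guard discrete extensivity at the half-voxel level
    closed = ndimage.binary_fill_holes(closed)
    lab, n = ndimage.label(closed, structure=_CONN26)
    if n > 1:
        sizes = ndimage.sum_labels(closed, lab, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        log.warning(
            "ganglion_mask components=%d kept_fraction=%.3f", n, sizes.max() / sizes.sum()
        )
        closed = lab == keep
    return closed


def taubin_smooth(
    mesh: trimesh.Trimesh, iterations: int = 10, lamb: float = 0.5, mu: float = -0.53
) -> trimesh.Trimesh:
    """Taubin's non-shrinking smoothing (alternating λ > 0, µ < 0 passes).

    Vertex and face counts are preserved; ``iterations == 0`` returns an
    identical copy.
    """
    if not (lamb > 0 and mu < 0 and abs(mu) > lamb):
        raise ValueError("Taubin smoothing requires lamb > 0, mu < 0, |mu| > lamb")
    out = trimesh.Trimesh(
        vertices=mesh.vertices.copy(), faces=mesh.faces.copy(), process=False
    )
    if iterations > 0:
        trimesh.smoothing.filter_taubin(out, lamb=lamb, nu=abs(mu), iterations=iterations)
    return out


def ganglion_surface(
    mask: np.ndarray,
    spacing_um,
    smoothing_iters: int = 10,
    lambda_mu: tuple[float, float] = (0.5, -0.53),
) -> SurfaceModel:
    """Smoothed ganglionic surface mesh from a solid binary mask."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    raw = binary_mesh(mask, spacing_um)
    lamb, mu = lambda_mu
    smoothed = taubin_smooth(raw, iterations=smoothing_iters, lamb=lamb, mu=mu)
    digest = hashlib.sha256(np.packbits(mask).tobytes()).hexdigest()[:16]
    return SurfaceModel(
        mesh=smoothed,
        source_mask_hash=digest,
        smoothing_params={"iterations": smoothing_iters, "lambda": lamb, "mu": mu},
    )


def mesh_open_edge_count(mesh: trimesh.Trimesh) -> int:
    """Number of edges not shared by exactly two faces."""
    edges = np.sort(mesh.edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int(np.sum(counts != 2))


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume (µm³) by the divergence theorem.

    Sums signed tetrahedra spanned by each face and the origin; the
    absolute value makes the result independent of global orientation,
    and the signed sum itself is invariant to rigid motion.
    """
    if len(mesh.faces) == 0:
        raise ValueError("mesh has no faces")
    open_edges = mesh_open_edge_count(mesh)
    if open_edges:
        raise ValueError(f"mesh is not watertight: {open_edges} open edges")
    verts = mesh.vertices.view(np.ndarray)
    # reference point at the centroid, not the origin: keeps the signed
    # tetrahedra well-conditioned for meshes far from the origin
    tri = (verts - verts.mean(axis=0))[mesh.faces]
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    return float(abs(signed.sum()))


def voxel_volume(volume: LabelVolume, cell_id: int) -> float:
    """Exact voxel-count volume (µm³) of one label."""
    n = int(np.count_nonzero(volume.labels == cell_id))
    if n == 0:
        avail = volume.label_ids()
        head = ", ".join(map(str, avail[:20]))
        more = "..." if len(avail) > 20 else ""
        raise KeyError(f"label {cell_id} not in volume (available: {head}{more})")
    return n * volume.voxel_volume_um3
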