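"""Synaptic apposition surface (SAS) extraction and morphometry.

The SAS of a junction object is taken as the mid-surface of its voxel
slab: junction voxels are projected onto the slab's principal plane, an
occupancy grid in that plane is closed morphologically (to bridge the
20 nm section-sampling gaps of the anisotropic grid), and a height-field
triangulation over the occupied cells gives the surface.  Metrics
(area, perimeter, curvature ratio) and the tissue-shrinkage correction
are computed on the resulting mesh.

Shrinkage convention: the processing shrinkage factor is an *area* ratio
p^2 (area after / area before EM processing, 0.933 here), so corrected
areas are ``area / p^2`` and corrected lengths ``length / p``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk, remove_small_holes, \
    remove_small_objects

from .mesh import SASMesh
from .volume import LabeledVolume

#: area shrinkage factor p^2 due to EM tissue processing
DEFAULT_SHRINKAGE_P2 = 0.933

#: PSD mean-thickness decision boundary between thin (symmetric) and
#: prominent (asymmetric) densities, nm
DEFAULT_THICKNESS_THRESHOLD_NM = 30.0

AS = "AS"
SS = "SS"
INDETERMINATE = "indeterminate"


class EmptyMeshError(ValueError):
    pass


@dataclass(frozen=True)
class SASMetrics:
    """Morphometric summary of one SAS.

    area / perimeter are raw mesh measurements in nm^2 / nm; the
    ``corrected_*`` fields are rescaled to pre-processing tissue
    dimensions by the area shrinkage factor p^2 (areas / p^2,
    lengths / p).  ``curvature`` is the dimensionless ratio of the RMS
    orthogonal deviation of the surface from its best-fit plane to
    sqrt(area); it is 0 for a flat surface and invariant under rigid
    motion and uniform scaling.
    """

    area: float
    perimeter: float
    curvature: float
    corrected_area: float
    corrected_perimeter: float


def fit_plane(vertices: np.ndarray,
              weights: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Weighted total-least-squares plane through a point set.

    Returns ``(centroid, unit_normal)``; the normal is the eigenvector of
    the weighted covariance with the smallest eigenvalue.
    """
    pts = np.asarray(vertices, dtype=float)
    if weights is None:
        weights = np.ones(len(pts))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    centroid = w @ pts
    d = pts - centroid
    cov = (d * w[:, None]).T @ d
    evals, evecs = np.linalg.eigh(cov)
    return centroid, evecs[:, 0]


def vertex_area_weights(mesh: SASMesh) -> np.ndarray:
    """Per-vertex weight = one third of incident triangle areas."""
    if "vertex_weights" not in mesh._edge_cache:
        v = mesh.vertices
        f = mesh.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        tri_area = 0.5 * np.sqrt((cr * cr).sum(axis=1))
        w = np.zeros(len(v))
        for k in range(3):
            np.add.at(w, f[:, k], tri_area / 3.0)
        mesh._edge_cache["vertex_weights"] = w
    return mesh._edge_cache["vertex_weights"]


def mesh_area(mesh: SASMesh) -> float:
    if "area" not in mesh._edge_cache:
        v, f = mesh.vertices, mesh.faces
        if not len(f):
            return 0.0
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        mesh._edge_cache["area"] = float(
            0.5 * np.sqrt((cr * cr).sum(axis=1)).sum())
    return mesh._edge_cache["area"]


def mesh_perimeter(mesh: SASMesh) -> float:
    """Total length of all boundary loops (holes add perimeter)."""
    total = 0.0
    for loop in mesh.boundary_loops():
        pts = mesh.vertices[loop]
        seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        total += float(np.linalg.norm(seg, axis=1).sum())
    return total


def mesh_curvature_ratio(mesh: SASMesh) -> float:
    """RMS plane deviation divided by sqrt(area), dimensionless >= 0."""
    area = mesh_area(mesh)
    if area <= 0:
        raise EmptyMeshError("cannot compute curvature of a zero-area mesh")
    w = vertex_area_weights(mesh)
    used = w > 0
    centroid, normal = fit_plane(mesh.vertices[used], w[used])
    dev = (mesh.vertices[used] - centroid) @ normal
    wn = w[used] / w[used].sum()
    rms = float(np.sqrt(np.sum(wn * dev ** 2)))
    return rms / np.sqrt(area)


def compute_metrics(mesh: SASMesh,
                    shrinkage_p2: float = DEFAULT_SHRINKAGE_P2) -> SASMetrics:
    """Area, perimeter and curvature of a SAS, with shrinkage correction."""
    if mesh.is_empty():
        raise EmptyMeshError("cannot compute metrics of an empty mesh")
    if not (0 < shrinkage_p2 <= 1):
        raise ValueError("shrinkage_p2 must be in (0, 1]")
    area = mesh_area(mesh)
    perim = mesh_perimeter(mesh)
    curv = mesh_curvature_ratio(mesh)
    p = np.sqrt(shrinkage_p2)
    return SASMetrics(
        area=area,
        perimeter=perim,
        curvature=curv,
        corrected_area=area / shrinkage_p2,
        corrected_perimeter=perim / p,
    )


# ---------------------------------------------------------------------------
# SAS extraction from a labeled volume
# ---------------------------------------------------------------------------

def _principal_frame(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and principal axes (columns; last = thinnest = normal)."""
    centroid = pts.mean(axis=0)
    d = pts - centroid
    cov = d.T @ d / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    # eigh: ascending eigenvalues -> evecs[:,0] is the slab normal
    frame = np.column_stack([evecs[:, 2], evecs[:, 1], evecs[:, 0]])
    return centroid, frame


def _heightfield_mesh(occ: np.ndarray, height: np.ndarray,
                      origin_uv: np.ndarray, cell: float,
                      centroid: np.ndarray, frame: np.ndarray,
                      synapse_id: int | None) -> SASMesh:
    """Triangulate occupied grid cells of a mid-surface height field."""
    nu, nv = occ.shape
    vid = -np.ones(occ.shape, dtype=np.int64)
    iu, iv = np.nonzero(occ)
    vid[iu, iv] = np.arange(len(iu))
    u = origin_uv[0] + (iu + 0.5) * cell
    v = origin_uv[1] + (iv + 0.5) * cell
    h = height[iu, iv]
    verts = (centroid[None, :]
             + u[:, None] * frame[:, 0][None, :]
             + v[:, None] * frame[:, 1][None, :]
             + h[:, None] * frame[:, 2][None, :])
    # 2x2 blocks: quad -> 2 triangles; 3 occupied corners -> 1 triangle
    a = vid[:-1, :-1].ravel()
    b = vid[1:, :-1].ravel()
    c = vid[1:, 1:].ravel()
    d = vid[:-1, 1:].ravel()
    corners = np.stack([a, b, c, d])
    nocc = (corners >= 0).sum(axis=0)
    full = nocc == 4
    tris = [np.column_stack([a[full], b[full], c[full]]),
            np.column_stack([a[full], c[full], d[full]])]
    three = nocc == 3
    if three.any():
        sub = corners[:, three]  # shape (4, m), one entry == -1 per column
        order = np.argsort(sub < 0, axis=0, kind="stable")
        kept = np.take_along_axis(sub, order[:3], axis=0)
        tris.append(kept.T)
    faces = np.vstack([t for t in tris if len(t)]) if tris else \
        np.empty((0, 3), np.int64)
    if not len(faces):
        # degenerate object (line or point of cells): emit a minimal
        # two-triangle strip spanning the occupied extent so that callers
        # always receive a valid mesh
        lo = np.array([u.min() - cell / 2, v.min() - cell / 2])
        hi = np.array([u.max() + cell / 2, v.max() + cell / 2])
        hmean = float(h.mean())
        corners_uv = [(lo[0], lo[1]), (hi[0], lo[1]),
                      (hi[0], hi[1]), (lo[0], hi[1])]
        verts = np.array([
            centroid + cu * frame[:, 0] + cv * frame[:, 1] + hmean * frame[:, 2]
            for cu, cv in corners_uv
        ])
        faces = [(0, 1, 2), (0, 2, 3)]
    return SASMesh(vertices=verts, faces=np.asarray(faces, dtype=np.int64),
                   synapse_id=synapse_id)


def extract_sas(vol: LabeledVolume, synapse_id: int,
                closing_radius_cells: int = 2) -> SASMesh:
    """Mid-surface mesh of a junction object.

    The object's voxel centers (in nm) are projected onto the slab's
    principal plane; occupancy is rasterised at the in-plane voxel pitch,
    morphologically closed to bridge anisotropic sampling gaps, and the
    per-cell mean offset along the slab normal gives the mid-surface
    height field, which is triangulated.

    Raises :class:`~sasmorph.volume.UnknownObjectError` for an unknown ID
    and :class:`EmptyMeshError` for an object with no voxels.
    """
    pts = vol.voxel_centers_nm(synapse_id)  # raises UnknownObjectError
    if len(pts) == 0:
        raise EmptyMeshError(f"object {synapse_id} has no voxels")
    cell = float(min(vol.voxel_size_nm))
    if len(pts) < 3:
        centroid = pts.mean(axis=0)
        frame = np.eye(3)
    else:
        centroid, frame = _principal_frame(pts)
    loc = (pts - centroid) @ frame  # columns: u, v, h
    u, v, h = loc[:, 0], loc[:, 1], loc[:, 2]
    pad = 2 + closing_radius_cells
    origin = np.array([u.min() - pad * cell, v.min() - pad * cell])
    iu = np.floor((u - origin[0]) / cell).astype(int)
    iv = np.floor((v - origin[1]) / cell).astype(int)
    nu = iu.max() + 1 + pad
    nv = iv.max() + 1 + pad
    counts = np.zeros((nu, nv))
    hsum = np.zeros((nu, nv))
    np.add.at(counts, (iu, iv), 1.0)
    np.add.at(hsum, (iu, iv), h)
    occ = counts > 0
    closed = closing(occ, disk(closing_radius_cells))
    # suppress sampling artifacts: stray cells and pinholes far below the
    # smallest biologically meaningful perforation (~80 nm across)
    min_hole_cells = max(1, int(np.ceil(5000.0 / cell ** 2)))
    closed = remove_small_objects(closed, max_size=31)
    closed = remove_small_holes(closed, max_size=min_hole_cells - 1)
    if not closed.any():
        closed = occ
    # mid-surface height: local mean of sample offsets, smoothed over a
    # few cells to suppress section-quantisation roughness that would
    # otherwise inflate the surface area
    win = 2 * closing_radius_cells + 1
    csm = ndimage.uniform_filter(counts, size=win)
    hsm = ndimage.uniform_filter(hsum, size=win)
    height = np.zeros((nu, nv))
    have = csm > 0
    height[have] = hsm[have] / csm[have]
    filled = closed & ~have
    if filled.any():
        # nearest-sample height for cells beyond the smoothing support
        _, (ni, nj) = ndimage.distance_transform_edt(
            ~have, return_indices=True
        )
        height[filled] = height[ni[filled], nj[filled]]
    return _heightfield_mesh(closed, height, origin, cell, centroid, frame,
                             synapse_id=int(synapse_id))


# ---------------------------------------------------------------------------
# AS / SS classification by PSD thickness
# ---------------------------------------------------------------------------

def psd_mean_thickness(vol: LabeledVolume, synapse_id: int,
                       mesh: SASMesh | None = None) -> float:
    """Mean slab thickness along the local normal, nm.

    Computed as object voxel volume divided by mid-surface area; returns
    ``nan`` when the area is too small to be meaningful.
    """
    pts = vol.voxel_centers_nm(synapse_id)
    if mesh is None:
        mesh = extract_sas(vol, synapse_id)
    area = mesh_area(mesh)
    dx, dy, dz = vol.voxel_size_nm
    voxvol = dx * dy * dz
    if area <= 4 * dx * dy or len(pts) < 4:
        return float("nan")
    return len(pts) * voxvol / area


def classify_type(vol: LabeledVolume, synapse_id: int,
                  thickness_threshold: float = DEFAULT_THICKNESS_THRESHOLD_NM,
                  mesh: SASMesh | None = None) -> str:
    """Asymmetric (prominent PSD) vs symmetric (thin PSD) junction type.

    Returns ``"AS"`` if the mean PSD slab thickness is >= the threshold,
    ``"SS"`` if below, and ``"indeterminate"`` when thickness cannot be
    measured (callers exclude these downstream and log the count).
    """
    t = psd_mean_thickness(vol, synapse_id, mesh=mesh)
    if not np.isfinite(t):
        return INDETERMINATE
    return AS if t >= thickness_threshold else SS
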