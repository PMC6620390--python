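"""Analytic SAS meshes of the four shape classes.

These are planar (optionally isometrically bent) triangulations used as
ground-truth inputs for the shape classifier and the morphometry oracles:
a macular SAS is a topological disk, a perforated one an annulus, a
horseshoe a C-shaped band (annulus minus a sector), and a fragmented one
two disjoint disks.
"""

from __future__ import annotations

import numpy as np

from ..mesh import SASMesh, merge_meshes
from ..geometry import mesh_area
from ..shapes import MACULAR, PERFORATED, HORSESHOE, FRAGMENTED, SHAPE_CLASSES


def _ring_patch(r_in: float, r_out: float, theta0: float, theta1: float,
                n_rad: int, n_seg: int) -> SASMesh:
    """Triangulated radial patch between two radii and two angles.

    A full circle (theta span of 2*pi) is closed seamlessly; ``r_in == 0``
    collapses the inner ring to a single center vertex.
    """
    closed = abs((theta1 - theta0) - 2 * np.pi) < 1e-12
    ntheta = n_seg if closed else n_seg + 1
    thetas = theta0 + (theta1 - theta0) * np.arange(ntheta) / (
        n_seg if closed else n_seg
    )
    radii = np.linspace(r_in, r_out, n_rad + 1)
    verts: list[tuple[float, float, float]] = []
    ring_ids: list[np.ndarray] = []
    for r in radii:
        if r == 0:
            verts.append((0.0, 0.0, 0.0))
            ring_ids.append(np.full(ntheta, len(verts) - 1))
            continue
        base = len(verts)
        for t in thetas:
            verts.append((r * np.cos(t), r * np.sin(t), 0.0))
        ring_ids.append(base + np.arange(ntheta))
    faces: list[tuple[int, int, int]] = []
    for i in range(n_rad):
        inner, outer = ring_ids[i], ring_ids[i + 1]
        for j in range(n_seg):
            j2 = (j + 1) % ntheta if closed else j + 1
            a, b = inner[j], inner[j2]
            c, d = outer[j2], outer[j]
            if a == b:  # degenerate inner ring (center vertex)
                faces.append((a, c, d))
            else:
                faces.append((a, c, d))
                faces.append((a, b, c))
    return SASMesh(np.asarray(verts, float), np.asarray(faces, np.int64))


def disk_mesh(radius: float, n_seg: int = 96, n_rad: int = 10) -> SASMesh:
    return _ring_patch(0.0, radius, 0.0, 2 * np.pi, n_rad, n_seg)


def annulus_mesh(r_in: float, r_out: float, n_seg: int = 96,
                 n_rad: int = 8) -> SASMesh:
    if not 0 < r_in < r_out:
        raise ValueError("need 0 < r_in < r_out")
    return _ring_patch(r_in, r_out, 0.0, 2 * np.pi, n_rad, n_seg)


def cband_mesh(r_in: float, r_out: float, gap_angle: float,
               n_seg: int = 96, n_rad: int = 8) -> SASMesh:
    """Annulus minus a sector of ``gap_angle`` radians (a C-shaped band)."""
    if not 0 < gap_angle < 2 * np.pi:
        raise ValueError("gap_angle must be in (0, 2*pi)")
    return _ring_patch(r_in, r_out, gap_angle / 2, 2 * np.pi - gap_angle / 2,
                       n_rad, n_seg)


def bend_cylindrical(mesh: SASMesh, bend_radius: float) -> SASMesh:
    """Isometrically roll a planar (z = 0) mesh onto a cylinder.

    Maps (x, y, 0) -> (R sin(x/R), y, R (1 - cos(x/R))); arc lengths, and
    hence area and perimeter, are preserved while the curvature ratio
    grows as the bend radius shrinks.
    """
    if bend_radius <= 0:
        raise ValueError("bend_radius must be positive")
    v = mesh.vertices
    R = float(bend_radius)
    x = v[:, 0] / R
    out = np.column_stack([R * np.sin(x), v[:, 1], R * (1 - np.cos(x))])
    return SASMesh(out, mesh.faces.copy(), synapse_id=mesh.synapse_id)


def generate_sas_mesh(shape_class: str, area_target: float,
                      rng_seed: int, bend_radius: float | None = None,
                      n_seg: int = 96) -> SASMesh:
    """Analytic SAS mesh of a given shape class and total area (nm^2).

    The mesh is scaled so its triangulated area equals ``area_target``
    (well within the 5% contract even before scaling) and randomly
    rotated in-plane with the seeded generator.  ``bend_radius`` (nm), if
    given, applies an isometric cylindrical bend, leaving the area
    unchanged.
    """
    if shape_class not in SHAPE_CLASSES:
        raise ValueError(f"unknown shape class {shape_class!r}")
    if area_target <= 0:
        raise ValueError("area_target must be positive")
    rng = np.random.default_rng(rng_seed)
    if shape_class == MACULAR:
        mesh = disk_mesh(1.0, n_seg=n_seg)
    elif shape_class == PERFORATED:
        mesh = annulus_mesh(0.4, 1.0, n_seg=n_seg)
    elif shape_class == HORSESHOE:
        mesh = cband_mesh(0.5, 1.0, gap_angle=np.deg2rad(100), n_seg=n_seg)
    else:  # fragmented: two disjoint disks carrying 60% / 40% of the area
        d1 = disk_mesh(np.sqrt(0.6), n_seg=n_seg)
        d2 = disk_mesh(np.sqrt(0.4), n_seg=n_seg)
        d2 = d2.transformed(translation=np.array([2.2, 0.0, 0.0]))
        mesh = merge_meshes([d1, d2])
    scale = np.sqrt(area_target / mesh_area(mesh))
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([
        [np.cos(theta), -np.sin(theta), 0.0],
        [np.sin(theta), np.cos(theta), 0.0],
        [0.0, 0.0, 1.0],
    ])
    mesh = mesh.transformed(rotation=rot, scale=scale)
    if bend_radius is not None:
        mesh = bend_cylindrical(mesh, bend_radius)
    return mesh
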