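"""Shape taxonomy of synaptic junctions: macular, perforated,
horseshoe-shaped, fragmented.

The classification is a fixed decision tree on the topology and boundary
geometry of the SAS mesh:

* >= 2 edge-connected components  -> **fragmented** (several PSDs with no
  connection between them; multiplicity dominates any other feature),
* >= 1 interior hole              -> **perforated**,
* deep boundary indentation       -> **horseshoe**,
* otherwise                       -> **macular** (continuous disk).

Holes are strictly topological (a closed interior boundary loop); a deep
indentation that still reaches the rim is never a hole.  The horseshoe
criterion is the maximal inward distance from the convex hull of the
flattened outline to the outline itself, normalised by the equivalent
disk radius sqrt(area/pi); the default threshold of 0.3 is a declared
operationalisation (the original taxonomy was applied by eye) and is
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .geometry import fit_plane, mesh_area, vertex_area_weights
from .mesh import SASMesh

MACULAR = "macular"
PERFORATED = "perforated"
HORSESHOE = "horseshoe"
FRAGMENTED = "fragmented"

SHAPE_CLASSES = (MACULAR, PERFORATED, HORSESHOE, FRAGMENTED)

#: indentation_depth_ratio at or above which a simply-connected SAS is
#: called horseshoe-shaped
DEFAULT_HORSESHOE_THRESHOLD = 0.3


@dataclass(frozen=True)
class ShapeCall:
    """Shape classification of one synapse with its evidence."""

    synapse_id: int | None
    shape_class: str
    n_components: int
    n_holes: int
    indentation_depth_ratio: float


def count_components(mesh: SASMesh) -> int:
    """Number of edge-connected triangle components."""
    return len(mesh.connected_components())


def count_holes(mesh: SASMesh) -> int:
    """Number of interior holes of a single-component genus-0 patch.

    Uses the Euler characteristic: for a connected surface of genus g
    with b boundary loops, chi = V - E + F = 2 - 2g - b, so a flat patch
    (g = 0) has b = 2 - chi boundary loops and b - 1 holes.  Raises on
    multi-component or non-manifold input.
    """
    mesh.check_manifold()
    if count_components(mesh) != 1:
        raise ValueError("count_holes requires a single-component mesh")
    chi = mesh.euler_characteristic()
    holes = 1 - chi
    if holes < 0:
        raise ValueError(f"unexpected Euler characteristic {chi} (> 1)")
    return int(holes)


def _flattened_boundary(mesh: SASMesh) -> np.ndarray:
    """Boundary vertices projected onto the area-weighted LSQ plane."""
    w = vertex_area_weights(mesh)
    used = w > 0
    centroid, normal = fit_plane(mesh.vertices[used], w[used])
    # in-plane basis
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    bverts = np.unique(mesh.boundary_edges())
    pts = mesh.vertices[bverts] - centroid
    return np.column_stack([pts @ e1, pts @ e2])


def indentation_depth(mesh: SASMesh) -> float:
    """Deepest boundary indentation, relative to the equivalent radius.

    The boundary is flattened onto the best-fit plane; the depth is the
    maximal distance from a boundary point to the convex hull outline of
    all boundary points, divided by sqrt(area/pi).  Convex outlines give
    0.  Requires a single-component mesh without holes.
    """
    if count_components(mesh) != 1:
        raise ValueError("indentation_depth requires a single component")
    if count_holes(mesh) != 0:
        raise ValueError("indentation_depth requires a hole-free mesh")
    area = mesh_area(mesh)
    if area <= 0:
        raise ValueError("zero-area mesh")
    pts2 = _flattened_boundary(mesh)
    hull = shapely.convex_hull(shapely.multipoints(pts2))
    if hull.geom_type != "Polygon":  # collinear boundary: degenerate
        return 0.0
    rim = hull.exterior
    depth = float(shapely.distance(rim, shapely.points(pts2)).max())
    return float(depth / np.sqrt(area / np.pi))


def classify_shape(
    mesh: SASMesh,
    horseshoe_threshold: float = DEFAULT_HORSESHOE_THRESHOLD,
) -> ShapeCall:
    """Assign the mesh to exactly one of the four shape classes."""
    if mesh.is_empty():
        raise ValueError("cannot classify an empty mesh")
    comps = mesh.connected_components()
    n_comp = len(comps)
    if n_comp >= 2:
        holes = 0
        for comp in comps:
            try:
                holes += count_holes(mesh.submesh(comp))
            except ValueError:
                pass
        return ShapeCall(mesh.synapse_id, FRAGMENTED, n_comp, holes,
                         float("nan"))
    holes = count_holes(mesh)
    if holes >= 1:
        return ShapeCall(mesh.synapse_id, PERFORATED, 1, holes, float("nan"))
    ratio = indentation_depth(mesh)
    cls = HORSESHOE if ratio >= horseshoe_threshold else MACULAR
    return ShapeCall(mesh.synapse_id, cls, 1, 0, ratio)
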