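"""Triangulated synaptic apposition surfaces (SAS) and their topology.

The SAS is an open triangulated surface (a surface with boundary, not a
closed solid) representing the apposition between the pre- and postsynaptic
membranes.  Shape classification of a synapse reads off three topological /
geometric quantities of this surface: the number of edge-connected
components, the number of interior holes, and the depth of the deepest
boundary indentation.  This module owns the mesh container and the
topological primitives; metric quantities (area, perimeter, curvature) live
in :mod:`sasmorph.geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MeshTopologyError(ValueError):
    """Raised when a mesh violates the edge-manifold contract."""


@dataclass
class SASMesh:
    """An open triangle mesh in nanometre coordinates.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in nm.
    faces : (m, 3) int array
        Vertex index triples (counter-clockwise seen from the "presynaptic"
        side; orientation is not relied upon by any classifier).
    synapse_id : int or None
        Identifier of the junction object this surface was extracted from.
    """

    vertices: np.ndarray
    faces: np.ndarray
    synapse_id: int | None = None
    _edge_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh vertices must be finite")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    # -- basic counts -----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        """Number of vertices referenced by at least one face."""
        if not self.faces.size:
            return 0
        return int(np.unique(self.faces).size)

    @property
    def n_faces(self) -> int:
        return int(len(self.faces))

    def is_empty(self) -> bool:
        return self.n_faces == 0

    # -- edges ------------------------------------------------------------

    def _edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unique undirected edges, inverse map, and per-edge face counts."""
        if "edges" not in self._edge_cache:
            raw = self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
            lo = raw.min(axis=1).astype(np.int64)
            hi = raw.max(axis=1).astype(np.int64)
            keys = lo * len(self.vertices) + hi
            ukeys, inv, counts = np.unique(
                keys, return_inverse=True, return_counts=True)
            edges = np.column_stack([ukeys // len(self.vertices),
                                     ukeys % len(self.vertices)])
            self._edge_cache["edges"] = (edges, inv, counts)
        return self._edge_cache["edges"]

    @property
    def n_edges(self) -> int:
        return int(len(self._edges()[0]))

    def check_manifold(self) -> None:
        """Raise :class:`MeshTopologyError` if any edge bounds > 2 faces."""
        edges, _, counts = self._edges()
        bad = counts > 2
        if np.any(bad):
            offenders = [tuple(e) for e in edges[bad][:10]]
            raise MeshTopologyError(
                f"non-manifold edges (shared by >2 triangles): {offenders}"
            )

    def boundary_edges(self) -> np.ndarray:
        """Undirected edges that belong to exactly one triangle, (k, 2)."""
        edges, _, counts = self._edges()
        return edges[counts == 1]

    # -- topology ---------------------------------------------------------

    def connected_components(self) -> list[np.ndarray]:
        """Face index arrays of edge-connected triangle components."""
        if self.is_empty():
            raise ValueError("empty mesh has no components")
        if "components" not in self._edge_cache:
            from scipy import sparse
            from scipy.sparse.csgraph import connected_components as _cc

            _, inv, _ = self._edges()
            # faces sharing an edge id become graph neighbours
            order = np.argsort(inv, kind="stable")
            flat = inv[order]
            face_ids = order // 3
            same = flat[1:] == flat[:-1]
            a = face_ids[:-1][same]
            b = face_ids[1:][same]
            n = self.n_faces
            g = sparse.coo_matrix(
                (np.ones(len(a)), (a, b)), shape=(n, n))
            _, labels = _cc(g, directed=False)
            self._edge_cache["components"] = [
                np.flatnonzero(labels == r) for r in np.unique(labels)]
        return self._edge_cache["components"]

    def euler_characteristic(self) -> int:
        """chi = V - E + F, counting only face-referenced vertices."""
        if self.is_empty():
            raise ValueError("empty mesh has no Euler characteristic")
        return self.n_vertices - self.n_edges + self.n_faces

    def boundary_loops(self) -> list[np.ndarray]:
        """Closed vertex cycles of the boundary, one array per loop.

        Requires an edge-manifold mesh.  At a vertex shared by several
        boundary loops (a pinch point) the walk picks an arbitrary
        continuation; such meshes do not arise from the generators here.
        """
        self.check_manifold()
        be = self.boundary_edges()
        if not len(be):
            return []
        # adjacency: vertex -> neighbouring boundary vertices
        adj: dict[int, list[int]] = {}
        for a, b in be:
            adj.setdefault(int(a), []).append(int(b))
            adj.setdefault(int(b), []).append(int(a))
        unused = {tuple(sorted((int(a), int(b)))) for a, b in be}
        loops: list[np.ndarray] = []
        while unused:
            a, b = next(iter(unused))
            loop = [a, b]
            unused.discard((a, b) if a < b else (b, a))
            while True:
                cur, prev = loop[-1], loop[-2]
                nxt = None
                for cand in adj[cur]:
                    key = (cur, cand) if cur < cand else (cand, cur)
                    if cand != prev and key in unused:
                        nxt = cand
                        unused.discard(key)
                        break
                if nxt is None:
                    break
                if nxt == loop[0]:
                    break
                loop.append(nxt)
            loops.append(np.asarray(loop, dtype=np.int64))
        return loops

    # -- submesh ----------------------------------------------------------

    def submesh(self, face_idx: np.ndarray) -> "SASMesh":
        """Mesh restricted to the given faces, with vertices compacted."""
        faces = self.faces[np.asarray(face_idx)]
        used, inv = np.unique(faces, return_inverse=True)
        return SASMesh(
            vertices=self.vertices[used],
            faces=inv.reshape(-1, 3),
            synapse_id=self.synapse_id,
        )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    scale: float = 1.0) -> "SASMesh":
        """Rigidly moved and/or uniformly scaled copy."""
        v = self.vertices * float(scale)
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return SASMesh(vertices=v, faces=self.faces.copy(),
                       synapse_id=self.synapse_id)


def save_mesh(mesh: SASMesh, path) -> None:
    """Write a mesh to OFF or PLY (chosen by file extension)."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    tm.export(str(path))


def load_mesh(path, synapse_id: int | None = None) -> SASMesh:
    """Read a mesh from OFF/PLY into an :class:`SASMesh`."""
    import trimesh

    tm = trimesh.load_mesh(str(path), process=False)
    return SASMesh(np.asarray(tm.vertices, float),
                   np.asarray(tm.faces, np.int64), synapse_id=synapse_id)


def merge_meshes(meshes: list[SASMesh], synapse_id: int | None = None) -> SASMesh:
    """Disjoint union of several meshes into one (multi-component) mesh."""
    if not meshes:
        raise ValueError("nothing to merge")
    verts, faces, off = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + off)
        off += len(m.vertices)
    return SASMesh(np.vstack(verts), np.vstack(faces), synapse_id=synapse_id)
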