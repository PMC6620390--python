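"""Topology of SAS meshes: components, holes, boundary loops, manifoldness."""

import numpy as np
import networkx as nx
import pytest

from sasmorph.mesh import MeshTopologyError, SASMesh, merge_meshes
from sasmorph.shapes import (classify_shape, count_components, count_holes,
                             indentation_depth)
from sasmorph.synthetic.meshes import (annulus_mesh, cband_mesh, disk_mesh,
                                       generate_sas_mesh)


def test_disk_is_a_topological_disk():
    d = disk_mesh(500.0)
    assert count_components(d) == 1
    assert count_holes(d) == 0
    assert d.euler_characteristic() == 1
    assert len(d.boundary_loops()) == 1


def test_annulus_topology():
    a = annulus_mesh(200.0, 500.0)
    assert a.euler_characteristic() == 0
    assert count_holes(a) == 1
    assert len(a.boundary_loops()) == 2


def test_two_disjoint_disks():
    m = merge_meshes([disk_mesh(300.0),
                      disk_mesh(200.0).transformed(
                          translation=np.array([2000.0, 0, 0]))])
    assert count_components(m) == 2


def test_component_count_matches_union_find_oracle(rng):
    """Random disjoint patches, against a networkx component oracle."""
    n = 5
    parts = []
    for i in range(n):
        d = disk_mesh(rng.uniform(50, 150), n_seg=24, n_rad=3)
        parts.append(d.transformed(
            translation=np.array([i * 1000.0, rng.uniform(0, 200), 0])))
    m = merge_meshes(parts)
    assert count_components(m) == n
    # oracle: graph over faces connected by shared (sorted) edges
    g = nx.Graph()
    g.add_nodes_from(range(m.n_faces))
    edge_to_faces = {}
    for fi, f in enumerate(m.faces):
        for k in range(3):
            e = tuple(sorted((f[k], f[(k + 1) % 3])))
            edge_to_faces.setdefault(e, []).append(fi)
    for faces in edge_to_faces.values():
        for a, b in zip(faces, faces[1:]):
            g.add_edge(a, b)
    assert nx.number_connected_components(g) == n


def test_punched_disk_hole_count_against_loop_tracing():
    """Removing 3 interior patches of faces creates 3 holes; the
    Euler-characteristic count must agree with boundary-loop tracing."""
    d = disk_mesh(500.0, n_seg=96, n_rad=12)
    centers = np.array([[250, 0, 0], [-150, 220, 0], [-120, -260, 0]], float)
    tri_centers = d.vertices[d.faces].mean(axis=1)
    keep = np.ones(len(d.faces), bool)
    for c in centers:
        keep &= np.linalg.norm(tri_centers - c, axis=1) > 60.0
    punched = SASMesh(d.vertices, d.faces[keep])
    assert count_components(punched) == 1
    n_loops = len(punched.boundary_loops())
    assert count_holes(punched) == 3
    assert n_loops - 1 == 3


def test_nonmanifold_edge_is_reported():
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, -1, 0],
                      [0, 0, 1]], float)
    faces = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]])
    with pytest.raises(MeshTopologyError):
        SASMesh(verts, faces).check_manifold()


def test_empty_mesh_errors():
    empty = SASMesh(np.empty((0, 3)), np.empty((0, 3), dtype=int))
    with pytest.raises(ValueError):
        count_components(empty)
    with pytest.raises(ValueError):
        classify_shape(empty)


@pytest.mark.parametrize("shape", ["macular", "perforated", "horseshoe",
                                   "fragmented"])
def test_generated_meshes_classify_as_requested(shape):
    mesh = generate_sas_mesh(shape, 1.5e5, rng_seed=3)
    assert classify_shape(mesh).shape_class == shape


@pytest.mark.parametrize("shape", ["macular", "perforated", "horseshoe",
                                   "fragmented"])
def test_classification_invariant_under_rigid_motion_and_scale(shape, rng):
    mesh = generate_sas_mesh(shape, 2.0e5, rng_seed=11)
    # random rotation via QR decomposition
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    moved = mesh.transformed(rotation=q, translation=rng.normal(size=3) * 1e4,
                             scale=3.7)
    assert classify_shape(moved).shape_class == \
        classify_shape(mesh).shape_class


def test_exactly_one_class_per_mesh():
    """Decision tree is exhaustive and exclusive by construction; the
    evidence fields must be consistent with the class."""
    for shape in ["macular", "perforated", "horseshoe", "fragmented"]:
        call = classify_shape(generate_sas_mesh(shape, 1e5, rng_seed=5))
        if call.shape_class == "fragmented":
            assert call.n_components >= 2
        elif call.shape_class == "perforated":
            assert call.n_components == 1 and call.n_holes >= 1
        elif call.shape_class == "horseshoe":
            assert call.n_holes == 0 and call.indentation_depth_ratio >= 0.3
        else:
            assert call.indentation_depth_ratio < 0.3


def test_fragmented_dominates_holes():
    """Pieces with holes are still a fragmented synapse (multiplicity
    dominates the taxonomy)."""
    a = annulus_mesh(100.0, 250.0)
    b = annulus_mesh(100.0, 250.0).transformed(
        translation=np.array([1000.0, 0, 0]))
    m = merge_meshes([a, b])
    call = classify_shape(m)
    assert call.shape_class == "fragmented"
    assert call.n_holes == 2


def test_indentation_zero_for_convex_outlines():
    assert indentation_depth(disk_mesh(400.0)) < 0.02
    # square outline
    verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                      [0.5, 0.5, 0]], float) * 100
    faces = np.array([[0, 1, 4], [1, 2, 4], [2, 3, 4], [3, 0, 4]])
    assert indentation_depth(SASMesh(verts, faces)) < 1e-9


def test_cband_indentation_exceeds_half():
    c = cband_mesh(0.6, 1.0, gap_angle=np.deg2rad(90))
    assert indentation_depth(c) > 0.5
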