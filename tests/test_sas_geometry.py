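"""SAS extraction and morphometry: areas, perimeters, curvature, shrinkage."""

import numpy as np
import pytest

from sasmorph.geometry import (DEFAULT_SHRINKAGE_P2, EmptyMeshError,
                               classify_type, compute_metrics, extract_sas,
                               mesh_area, mesh_curvature_ratio,
                               psd_mean_thickness, vertex_area_weights)
from sasmorph.mesh import SASMesh
from sasmorph.synthetic.meshes import (annulus_mesh, bend_cylindrical,
                                       disk_mesh, generate_sas_mesh)
from sasmorph.volume import LabeledVolume, ObjectInfo, UnknownObjectError


def test_disk_metrics_match_analytics():
    r = 500.0
    m = compute_metrics(disk_mesh(r))
    assert m.area == pytest.approx(np.pi * r ** 2, rel=0.01)
    assert m.perimeter == pytest.approx(2 * np.pi * r, rel=0.01)
    assert m.curvature < 1e-6


def test_shrinkage_correction_is_area_over_p2():
    m = compute_metrics(disk_mesh(300.0), shrinkage_p2=0.933)
    assert m.corrected_area == pytest.approx(m.area / 0.933)
    assert m.corrected_perimeter == pytest.approx(
        m.perimeter / np.sqrt(0.933))
    assert DEFAULT_SHRINKAGE_P2 == 0.933


def test_hole_perimeter_adds_to_total():
    r_in, r_out = 200.0, 500.0
    m = compute_metrics(annulus_mesh(r_in, r_out))
    assert m.perimeter == pytest.approx(2 * np.pi * (r_in + r_out), rel=0.01)


def test_perforated_perimeter_exceeds_macular_at_equal_area():
    area = 2.5e5
    per_m = compute_metrics(generate_sas_mesh("macular", area, 1)).perimeter
    per_p = compute_metrics(generate_sas_mesh("perforated", area, 1)).perimeter
    assert per_p > per_m


def test_metrics_invariant_under_rigid_motion(rng):
    mesh = generate_sas_mesh("horseshoe", 1.8e5, rng_seed=2)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    moved = mesh.transformed(rotation=q, translation=np.array([1e5, -3e4, 7]))
    a, b = compute_metrics(mesh), compute_metrics(moved)
    assert b.area == pytest.approx(a.area, rel=1e-6)
    assert b.perimeter == pytest.approx(a.perimeter, rel=1e-6)
    assert b.curvature == pytest.approx(a.curvature, abs=1e-9)


def test_curvature_matches_plane_fit_oracle():
    """Bent disk curvature against an independent eigen-decomposition
    plane-fit oracle on the same vertices."""
    mesh = bend_cylindrical(disk_mesh(500.0), bend_radius=1200.0)
    w = vertex_area_weights(mesh)
    used = w > 0
    pts = mesh.vertices[used]
    ww = w[used] / w[used].sum()
    centroid = ww @ pts
    d = pts - centroid
    cov = (d * ww[:, None]).T @ d
    evals, evecs = np.linalg.eigh(cov)
    normal = evecs[:, 0]
    rms = np.sqrt(np.sum(ww * (d @ normal) ** 2))
    expected = rms / np.sqrt(mesh_area(mesh))
    assert mesh_curvature_ratio(mesh) == pytest.approx(expected, rel=1e-9)


def test_curvature_increases_with_bend():
    disk = disk_mesh(500.0)
    curvatures = [mesh_curvature_ratio(bend_cylindrical(disk, R))
                  for R in [8000.0, 4000.0, 2000.0, 1000.0, 600.0]]
    assert all(b > a for a, b in zip(curvatures, curvatures[1:]))
    # isometric up to chord shortening of the polygonal mesh
    bent = bend_cylindrical(disk, 800.0)
    assert mesh_area(bent) == pytest.approx(mesh_area(disk), rel=1e-3)


def test_empty_mesh_metrics_error():
    with pytest.raises(EmptyMeshError):
        compute_metrics(SASMesh(np.empty((0, 3)), np.empty((0, 3), int)))


# ---------------------------------------------------------------------------
# extraction from labeled volumes
# ---------------------------------------------------------------------------

def _slab_volume(angle_deg: float = 0.0) -> LabeledVolume:
    """1000 x 1000 x 40 nm slab, optionally rotated in-plane."""
    nz, ny, nx = 16, 320, 320
    labels = np.zeros((nz, ny, nx), np.uint16)
    dx, dy, dz = 5.0, 5.0, 20.0
    x = (np.arange(nx) + 0.5) * dx - nx * dx / 2
    y = (np.arange(ny) + 0.5) * dy - ny * dy / 2
    z = (np.arange(nz) + 0.5) * dz - nz * dz / 2
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    th = np.deg2rad(angle_deg)
    u = X * np.cos(th) + Y * np.sin(th)
    v = -X * np.sin(th) + Y * np.cos(th)
    mask = (np.abs(u) < 500) & (np.abs(v) < 500) & (Z >= -20) & (Z < 20)
    labels[np.transpose(mask, (2, 1, 0))] = 1
    return LabeledVolume(labels, (dx, dy, dz), {1: ObjectInfo(1, "synapse")})


@pytest.mark.parametrize("angle", [0.0, 45.0])
def test_flat_slab_extraction_area(angle):
    vol = _slab_volume(angle)
    mesh = extract_sas(vol, 1)
    assert mesh_area(mesh) == pytest.approx(1e6, rel=0.05)


def test_slab_thickness_and_type():
    vol = _slab_volume()
    assert psd_mean_thickness(vol, 1) == pytest.approx(40.0, rel=0.1)
    assert classify_type(vol, 1) == "AS"


def test_unknown_object_raises():
    vol = _slab_volume()
    with pytest.raises(UnknownObjectError):
        extract_sas(vol, 99)


def test_degenerate_two_voxel_object_yields_valid_mesh():
    labels = np.zeros((4, 8, 8), np.uint16)
    labels[1, 3, 3:5] = 5
    vol = LabeledVolume(labels, (5, 5, 20), {5: ObjectInfo(5, "synapse")})
    mesh = extract_sas(vol, 5)
    assert mesh.n_faces >= 1
    assert np.all(np.isfinite(mesh.vertices))


def test_type_recovery_exact_on_scene(small_scene, small_records):
    vol, truth = small_scene
    by_id = {s.synapse_id: s for s in truth.synapses}
    df = small_records
    typed = df[df["type"].isin(["AS", "SS"])]
    for sid, row in typed.iterrows():
        assert row["type"] == by_id[sid].syn_type


def test_mesh_off_ply_roundtrip(tmp_path):
    from sasmorph.mesh import load_mesh, save_mesh
    mesh = generate_sas_mesh("horseshoe", 1.2e5, rng_seed=4)
    for ext in ("off", "ply"):
        p = tmp_path / f"m.{ext}"
        save_mesh(mesh, p)
        back = load_mesh(p)
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-3)
        assert np.array_equal(np.sort(back.faces, axis=1),
                              np.sort(mesh.faces, axis=1))
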