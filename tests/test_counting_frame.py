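"""Unbiased 3D counting frame: decisions, brute-force agreement, tiling."""

import numpy as np
import pytest

from sasmorph.counting import (COUNTED, NOT_COUNTED, CountingFrame,
                               cf_decision, count_in_frame)
from sasmorph.volume import LabeledVolume, ObjectInfo

VS = (5.0, 5.0, 20.0)


def _box_object(lo_idx, hi_idx):
    """Voxel centers (nm) of a solid box of voxel indices (x, y, z)."""
    xs = np.arange(lo_idx[0], hi_idx[0])
    ys = np.arange(lo_idx[1], hi_idx[1])
    zs = np.arange(lo_idx[2], hi_idx[2])
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    idx = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    return (idx + 0.5) * np.array(VS)


FRAME = CountingFrame((500.0, 500.0, 400.0), (1500.0, 1500.0, 1200.0))


def test_object_strictly_inside_is_counted():
    obj = _box_object((150, 150, 30), (160, 160, 35))
    assert cf_decision(obj, VS, FRAME) == COUNTED


def test_object_crossing_exclusion_face_is_not_counted():
    # crosses only the x-max face at 1500 nm (voxel index 300)
    obj = _box_object((295, 150, 30), (305, 160, 35))
    assert cf_decision(obj, VS, FRAME) == NOT_COUNTED


def test_object_touching_acceptance_face_is_counted():
    # box ending exactly at the x-min plane (voxel 100 starts at 500 nm)
    obj = _box_object((95, 150, 30), (100, 160, 35))
    assert cf_decision(obj, VS, FRAME) == COUNTED


def test_object_fully_outside_is_not_counted():
    obj = _box_object((10, 10, 2), (20, 20, 6))
    assert cf_decision(obj, VS, FRAME) == NOT_COUNTED


def test_empty_object_errors():
    with pytest.raises(ValueError):
        cf_decision(np.empty((0, 3)), VS, FRAME)


def brute_force_decision(centers, vs, frame):
    """Independent oracle: literal transcription of the counting rule on
    closed voxel boxes and bounded faces."""
    half = np.asarray(vs) / 2
    lo = centers - half
    hi = centers + half
    fmin = np.asarray(frame.min_nm)
    fmax = np.asarray(frame.max_nm)

    def box_hits_face(b_lo, b_hi, axis, coord):
        if not (b_lo[axis] <= coord <= b_hi[axis]):
            return False
        for a in range(3):
            if a == axis:
                continue
            if b_hi[a] < fmin[a] or b_lo[a] > fmax[a]:
                return False
        return True

    for b_lo, b_hi in zip(lo, hi):
        for axis in range(3):
            if box_hits_face(b_lo, b_hi, axis, fmax[axis]):
                return NOT_COUNTED
    for b_lo, b_hi in zip(lo, hi):
        for axis in range(3):
            if box_hits_face(b_lo, b_hi, axis, fmin[axis]):
                return COUNTED
        if np.all(b_hi > fmin) and np.all(b_lo < fmax):
            return COUNTED
    return NOT_COUNTED


def test_agreement_with_brute_force_on_random_objects(rng):
    n_agree = 0
    for _ in range(1000):
        lo = np.array([rng.integers(0, 380), rng.integers(0, 380),
                       rng.integers(0, 80)])
        size = rng.integers(1, 25, size=3)
        obj = _box_object(lo, lo + size)
        got = cf_decision(obj, VS, FRAME)
        want = brute_force_decision(obj, VS, FRAME)
        assert got == want
        n_agree += 1
    assert n_agree == 1000


def test_tiling_counts_each_convex_object_exactly_once(rng):
    """A 2x2x2 tiling of frames covering the interior counts every
    convex object away from the outer border exactly once."""
    bounds = np.array([400.0, 400.0, 400.0]), np.array([3600.0, 3600.0,
                                                        3600.0])
    mids = (bounds[0] + bounds[1]) / 2
    frames = []
    for ix in range(2):
        for iy in range(2):
            for iz in range(2):
                lo = [bounds[0][a] if (ix, iy, iz)[a] == 0 else mids[a]
                      for a in range(3)]
                hi = [mids[a] if (ix, iy, iz)[a] == 0 else bounds[1][a]
                      for a in range(3)]
                frames.append(CountingFrame(tuple(lo), tuple(hi)))
    for _ in range(300):
        # convex boxes strictly inside the tiled region
        lo_nm = rng.uniform(500, 3300, size=3)
        size_nm = rng.uniform(40, 250, size=3)
        lo_idx = np.floor(lo_nm / np.array(VS)).astype(int)
        hi_idx = np.ceil((lo_nm + size_nm) / np.array(VS)).astype(int)
        obj = _box_object(lo_idx, hi_idx)
        hits = sum(cf_decision(obj, VS, f) == COUNTED for f in frames)
        assert hits == 1


def test_translation_sweep_is_unbiased(rng):
    """Counts of a homogeneous point process per unit frame volume do not
    depend on frame position (within Poisson error)."""
    n_pts = 20000
    ext = np.array([4000.0, 4000.0, 4000.0])
    pts = rng.uniform(0, 1, size=(n_pts, 3)) * ext
    lam = n_pts / np.prod(ext)
    side = 1500.0
    for _ in range(10):
        origin = rng.uniform(200, 2200, size=3)
        frame = CountingFrame(tuple(origin), tuple(origin + side))
        count = sum(
            cf_decision(p[None, :], (1e-3, 1e-3, 1e-3), frame) == COUNTED
            for p in pts[np.all(np.abs(pts - origin - side / 2)
                                < side / 2 + 10, axis=1)])
        expect = lam * side ** 3
        assert abs(count - expect) < 5 * np.sqrt(expect)


def test_count_in_frame_matches_per_object_decisions(small_scene,
                                                     small_records):
    vol, truth = small_scene
    frame = CountingFrame.from_margins(vol, 300.0)
    counts = count_in_frame(vol, frame, small_records, by=["type"])
    manual = 0
    for s in truth.synapses:
        d = cf_decision(vol.voxel_centers_nm(s.synapse_id),
                        vol.voxel_size_nm, frame)
        manual += d == COUNTED
    assert counts.sum() == manual


def test_frame_validation():
    with pytest.raises(ValueError):
        CountingFrame((0, 0, 0), (0, 10, 10))
    labels = np.zeros((4, 4, 4), np.uint16)
    vol = LabeledVolume(labels, VS, {})
    bad = CountingFrame((0, 0, 0), (1e6, 1e6, 1e6))
    with pytest.raises(ValueError):
        count_in_frame(vol, bad)


def test_empty_scene_has_zero_counts():
    labels = np.zeros((8, 8, 8), np.uint16)
    vol = LabeledVolume(labels, VS, {})
    frame = CountingFrame((5, 5, 20), (35, 35, 140))
    counts = count_in_frame(vol, frame)
    assert counts.sum() == 0
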