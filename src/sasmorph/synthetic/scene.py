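"""Seeded generation of labeled 3D neuropil stacks with ground truth.

Geometry model: dendritic shafts are capsules running roughly along x;
spiny dendrites carry spines (thin cylindrical neck + spheroid head);
synaptic junctions are curved slabs conforming to the surface of their
postsynaptic target (head, neck or shaft), with the PSD thickness
encoding the synapse type (prominent = asymmetric, thin = symmetric)
and the slab's in-chart footprint encoding the shape class (full disk,
disk with a hole, disk minus a wedge, or two disjoint patches).

Objects are placed by rejection sampling against the already-painted
label volume; junction footprints back off geometrically under
persistent crowding so that dense scenes fill rather than fail, and a
hard retry cap turns genuinely impossible densities into a
:class:`PlacementError`.  All randomness flows through one seeded
generator, so identical configs give voxel-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..volume import (DENDRITIC_SHAFT, SPINE_HEAD, SPINE_NECK, SYNAPSE,
                      LabeledVolume, ObjectInfo)
from . import _kernels as K
from .config import SHAPE_CLASSES, TARGET_CLASSES, ScenarioConfig

_SHAPE_CODE = {"macular": K.MACULAR_CODE, "perforated": K.PERFORATED_CODE,
               "horseshoe": K.HORSESHOE_CODE,
               "fragmented": K.FRAGMENTED_CODE}

# expected fraction of the chart ellipse covered by each footprint
_SHAPE_AREA_FRACTION = {
    "macular": 1.0,
    "perforated": 1.0 - K.HOLE_FRAC ** 2,
    "horseshoe": 1.0 - (K.WEDGE_HALF_RAD / np.pi) * (1 - K.WEDGE_INNER ** 2),
    "fragmented": 2 * K.FRAG_RADIUS ** 2,
}

# spine / dendrite geometry, nm
_DENDRITE_RADIUS = (110.0, 140.0)
_NECK_RADIUS = 50.0
_NECK_LENGTH = (150.0, 250.0)
_HEAD_RADIUS = (100.0, 140.0)
_SHAFT_PATCH_UMAX = 300.0
_MIN_JUNCTION_VOXELS = 16
_MIN_PATCH_HALFWIDTH = 110.0   # below this no cutout fits; force macular


class PlacementError(RuntimeError):
    """Requested density could not be placed without overlap."""


@dataclass
class SynapseTruth:
    """Ground truth for one placed junction."""

    synapse_id: int
    syn_type: str
    shape_class: str
    target_class: str
    target_object_id: int
    parent_dendrite_id: int
    head_id: int | None
    neck_id: int | None
    psd_thickness_nm: float
    n_voxels: int
    est_area_nm2: float
    truncated: bool = False
    chain_truncated: bool = False


@dataclass
class SceneGroundTruth:
    """Per-synapse and per-object truth of one generated stack."""

    synapses: list[SynapseTruth]
    dendrite_spiny: dict[int, bool]
    object_truncated: dict[int, bool]
    config: ScenarioConfig
    spine_parent: dict[int, int] = field(default_factory=dict)

    def non_truncated(self) -> list[SynapseTruth]:
        """Synapses whose junction and spine chain are fully in-volume."""
        return [s for s in self.synapses if not s.chain_truncated]


# ---------------------------------------------------------------------------
# voxel canvas
# ---------------------------------------------------------------------------

class _Canvas:
    def __init__(self, config: ScenarioConfig):
        nx, ny, nz = config.volume_shape
        self.labels = np.zeros((nz, ny, nx), dtype=np.uint16)
        self.vsize = np.asarray(config.voxel_size_nm, dtype=float)
        self.extent = np.asarray(config.extent_nm, dtype=float)

    def bounds(self, lo: np.ndarray, hi: np.ndarray):
        """Clipped voxel index ranges (ix0, ix1, iy0, iy1, iz0, iz1)."""
        dx, dy, dz = self.vsize
        nz, ny, nx = self.labels.shape
        ix0 = max(0, int(np.floor(lo[0] / dx)))
        iy0 = max(0, int(np.floor(lo[1] / dy)))
        iz0 = max(0, int(np.floor(lo[2] / dz)))
        ix1 = min(nx, int(np.ceil(hi[0] / dx)) + 1)
        iy1 = min(ny, int(np.ceil(hi[1] / dy)) + 1)
        iz1 = min(nz, int(np.ceil(hi[2] / dz)) + 1)
        if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
            return None
        return ix0, ix1, iy0, iy1, iz0, iz1

    def erase(self, b, object_id: int) -> None:
        """Remove an object's voxels inside an index-bounds box."""
        ix0, ix1, iy0, iy1, iz0, iz1 = b
        region = self.labels[iz0:iz1, iy0:iy1, ix0:ix1]
        region[region == object_id] = 0

    def probe_blocked(self, pts_nm: np.ndarray, allowed: int) -> bool:
        """Cheap pre-check: is any probe point inside a foreign object?"""
        nz, ny, nx = self.labels.shape
        idx = np.floor(pts_nm / self.vsize).astype(int)
        inb = ((idx >= 0).all(axis=1)
               & (idx < np.array([nx, ny, nz])).all(axis=1))
        idx = idx[inb]
        if not len(idx):
            return False
        vals = self.labels[idx[:, 2], idx[:, 1], idx[:, 0]]
        bad = vals[(vals != 0) & (vals != allowed)]
        return bool(bad.size)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([0.0, 0.0, 1.0])
    if abs(d @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    b1 = _unit(np.cross(d, a))
    return b1, np.cross(d, b1)


def _patch_semiaxes(area: float, shape: str, v_max: float,
                    u_max: float) -> tuple[float, float, str]:
    """Fit ellipse semi-axes to the drawn area under surface limits.

    Returns (a_u, a_v, realised_shape); the shape falls back to macular
    when the surface is too narrow to carry a resolvable cutout.
    """
    frac = _SHAPE_AREA_FRACTION[shape]
    a_iso = np.sqrt(area / (np.pi * frac))
    a_v = min(a_iso, v_max)
    a_u = min(area / (np.pi * frac * a_v), u_max)
    if shape != "macular" and min(a_u, a_v) < _MIN_PATCH_HALFWIDTH:
        shape = "macular"
        a_iso = np.sqrt(area / np.pi)
        a_v = min(a_iso, v_max)
        a_u = min(area / (np.pi * a_v), u_max)
    return a_u, a_v, shape


def _cyl_bbox(anchor, d, r0, t, a_u, a_v):
    """Tight per-axis bbox of a cylinder-surface patch around its anchor."""
    ax_ext = a_u + t + 30.0
    th = min(a_v / r0, 1.2)
    lat_ext = max((r0 + t) * np.sin(min(th, np.pi / 2)),
                  r0 * (1 - np.cos(th)) + t) + 35.0
    half = np.abs(d) * ax_ext + np.sqrt(np.maximum(1 - d * d, 0)) * lat_ext
    return anchor - half, anchor + half


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

@dataclass
class _Dendrite:
    object_id: int
    p0: np.ndarray
    direction: np.ndarray
    b1: np.ndarray
    b2: np.ndarray
    radius: float
    spiny: bool
    u_range: tuple[float, float]


@dataclass
class _Head:
    object_id: int
    neck_id: int
    parent_id: int
    center: np.ndarray
    radius: float
    pole: np.ndarray
    n_synapses: int = 0
    bounds: tuple = ()       # (neck_bounds, head_bounds) for rollback


def generate_scene(config: ScenarioConfig) -> tuple[LabeledVolume,
                                                    SceneGroundTruth]:
    """Generate one labeled stack and its ground truth.

    Raises :class:`PlacementError` if the requested synapse density
    cannot be placed without overlap within the retry budget.
    """
    rng = np.random.default_rng(config.seed)
    canvas = _Canvas(config)
    labels = canvas.labels
    ext = canvas.extent
    dx, dy, dz = canvas.vsize
    voxvol = float(dx * dy * dz)
    objects: dict[int, ObjectInfo] = {}
    next_id = 1

    def new_object(semantic: str) -> int:
        nonlocal next_id
        oid = next_id
        next_id += 1
        objects[oid] = ObjectInfo(oid, semantic)
        return oid

    def place_capsule(p0, p1, r, allowed1, allowed2, paint_id):
        """Check-then-paint a capsule; returns (voxels, bounds) or None."""
        b = canvas.bounds(np.minimum(p0, p1) - r, np.maximum(p0, p1) + r)
        if b is None:
            return None
        n = K.capsule(labels, *b, dx, dy, dz, p0, p1, r,
                      allowed1, allowed2, 0, False)
        if n < 0:
            return None
        n = K.capsule(labels, *b, dx, dy, dz, p0, p1, r,
                      allowed1, allowed2, paint_id, True)
        return n, b

    # ---- dendrites ------------------------------------------------------
    n_d = config.n_dendrites
    n_aspiny = int(round(config.fraction_aspiny_dendrites * n_d))
    ny_cells = max(1, int(np.ceil(np.sqrt(n_d))))
    nz_cells = max(1, int(np.ceil(n_d / ny_cells)))
    cells = [(iy, iz) for iy in range(ny_cells) for iz in range(nz_cells)]
    rng.shuffle(cells)
    spiny_flags = np.array([i >= n_aspiny for i in range(n_d)])
    rng.shuffle(spiny_flags)
    dendrites: list[_Dendrite] = []
    for i in range(n_d):
        iy, iz = cells[i]
        for attempt in range(config.max_retries):
            cy = (iy + 0.5) / ny_cells * ext[1]
            cz = (iz + 0.5) / nz_cells * ext[2]
            cy += rng.uniform(-0.08, 0.08) * ext[1] / ny_cells
            cz += rng.uniform(-0.08, 0.08) * ext[2] / nz_cells
            tilt = 0.05 if attempt else 0.1
            d = _unit(np.array([1.0, rng.uniform(-tilt, tilt),
                                rng.uniform(-tilt, tilt)]))
            radius = rng.uniform(*_DENDRITE_RADIUS)
            p_base = np.array([0.0, cy, cz])
            u_lo, u_hi = -2 * radius, ext[0] / d[0] + 2 * radius
            oid = next_id
            placed = place_capsule(p_base + u_lo * d, p_base + u_hi * d,
                                   radius, 0, 0, oid)
            if placed is None:
                continue
            oid = new_object(DENDRITIC_SHAFT)
            b1, b2 = _perp_basis(d)
            dendrites.append(_Dendrite(oid, p_base, d, b1, b2, radius,
                                       bool(spiny_flags[i]), (u_lo, u_hi)))
            break
        else:
            raise PlacementError(
                f"dendrite {i} could not be placed without overlap after "
                f"{config.max_retries} retries; reduce n_dendrites or "
                "enlarge the volume")

    spiny_dendrites = [dd for dd in dendrites if dd.spiny]
    aspiny_dendrites = [dd for dd in dendrites if not dd.spiny]
    margin = config.edge_margin_nm
    heads: list[_Head] = []
    spine_parent: dict[int, int] = {}

    def _try_build_spine(dend: _Dendrite, scale: float = 1.0
                         ) -> _Head | None:
        """One attempt at growing a spine on a spiny dendrite.

        ``scale`` < 1 shrinks the spine under persistent crowding so
        dense scenes can still complete.
        """
        u0 = rng.uniform(margin, ext[0] - margin)
        phi = rng.uniform(0, 2 * np.pi)
        nvec = np.cos(phi) * dend.b1 + np.sin(phi) * dend.b2
        p_surf = dend.p0 + u0 * dend.direction + dend.radius * nvec
        L = rng.uniform(*_NECK_LENGTH) * scale
        Rh = rng.uniform(*_HEAD_RADIUS) * scale
        c_head = p_surf + (L + 0.75 * Rh) * nvec
        # keep the whole spine inside the stack so its tracing chain and
        # any junction on it stay unbroken
        pad = Rh + 80.0
        if np.any(c_head < pad) or np.any(c_head > ext - pad):
            return None
        probes = np.array([c_head, p_surf + 0.5 * L * nvec,
                           p_surf + L * nvec])
        if canvas.probe_blocked(probes, dend.object_id):
            return None
        p_neck0 = p_surf - 15.0 * nvec
        p_neck1 = p_surf + L * nvec
        # check both parts before painting either
        bn = canvas.bounds(np.minimum(p_neck0, p_neck1) - _NECK_RADIUS,
                           np.maximum(p_neck0, p_neck1) + _NECK_RADIUS)
        bh = canvas.bounds(c_head - Rh, c_head + Rh)
        if bn is None or bh is None:
            return None
        if K.capsule(labels, *bn, dx, dy, dz, p_neck0, p_neck1,
                     _NECK_RADIUS, dend.object_id, 0, 0, False) < 0:
            return None
        if K.capsule(labels, *bh, dx, dy, dz, c_head, c_head, Rh,
                     dend.object_id, 0, 0, False) < 0:
            return None
        nid = new_object(SPINE_NECK)
        hid = new_object(SPINE_HEAD)
        K.capsule(labels, *bn, dx, dy, dz, p_neck0, p_neck1,
                  _NECK_RADIUS, 0, 0, nid, True)
        K.capsule(labels, *bh, dx, dy, dz, c_head, c_head, Rh,
                  0, 0, hid, True)
        spine_parent[nid] = dend.object_id
        spine_parent[hid] = nid
        head = _Head(hid, nid, dend.object_id, c_head, Rh, nvec,
                     bounds=(bn, bh))
        heads.append(head)
        return head

    def rollback_spine(head: _Head) -> None:
        """Undo a freshly built spine whose junction could not be placed."""
        bn, bh = head.bounds
        canvas.erase(bh, head.object_id)
        canvas.erase(bn, head.neck_id)
        del objects[head.object_id]
        del objects[head.neck_id]
        del spine_parent[head.object_id]
        del spine_parent[head.neck_id]
        heads.remove(head)

    def build_spine(dend: _Dendrite, mandatory: bool) -> _Head | None:
        for _ in range(config.max_retries):
            head = _try_build_spine(dend)
            if head is not None:
                return head
        if mandatory:
            raise PlacementError(
                f"could not attach a spine to dendrite {dend.object_id} "
                f"after {config.max_retries} retries")
        return None

    n_synapses = config.n_synapses

    # decoy spines give every spiny dendrite its defining morphology
    if n_synapses > 0:
        for dend in spiny_dendrites:
            length_um = (dend.u_range[1] - dend.u_range[0]) * 1e-3
            n_spines = max(1, int(rng.poisson(
                config.spines_per_micron * length_um)))
            build_spine(dend, mandatory=True)
            for _ in range(n_spines - 1):
                build_spine(dend, mandatory=False)

    # ---- synapses -------------------------------------------------------
    truths: list[SynapseTruth] = []

    def place_cyl_junction(p0, dvec, b1, b2, r0, u0, phi0, t,
                           a_u, a_v, code, w0, allowed, sid):
        anchor = p0 + u0 * dvec + r0 * (np.cos(phi0) * b1
                                        + np.sin(phi0) * b2)
        lo, hi = _cyl_bbox(anchor, dvec, r0, t, a_u, a_v)
        b = canvas.bounds(lo, hi)
        if b is None:
            return None
        n = K.cylinder_patch(labels, *b, dx, dy, dz, p0, dvec, b1, b2,
                             r0, u0, phi0, t, a_u, a_v, code, w0,
                             allowed, 0, False)
        if n < 0:
            return None
        n = K.cylinder_patch(labels, *b, dx, dy, dz, p0, dvec, b1, b2,
                             r0, u0, phi0, t, a_u, a_v, code, w0,
                             allowed, sid, True)
        if n < _MIN_JUNCTION_VOXELS:
            canvas.erase(b, sid)
            return None
        return n

    for k in range(n_synapses):
        syn_type = "AS" if rng.random() < config.as_fraction else "SS"
        target_class = TARGET_CLASSES[
            rng.choice(4, p=np.asarray(config.target_mix[syn_type]))]
        shape = SHAPE_CLASSES[
            rng.choice(4, p=np.asarray(config.shape_mix[syn_type]))]
        mu, sigma = config.sas_area_lognormal[shape]
        drawn_area = float(rng.lognormal(mu, sigma))
        t = float(config.psd_thickness_nm[syn_type])
        w0 = rng.uniform(0, 2 * np.pi)

        placed = False
        for attempt in range(config.max_retries):
            # back off the footprint (and, late on, the spine size) under
            # persistent crowding so a dense scene fills rather than
            # failing; the realised area is what enters the ground truth
            area = drawn_area * max(0.3, 0.7 ** (attempt // 10))
            spine_scale = 1.0 if attempt < 150 else (
                0.85 if attempt < 300 else 0.7)

            if target_class in ("aspiny_shaft", "spiny_shaft"):
                pool = (aspiny_dendrites if target_class == "aspiny_shaft"
                        else spiny_dendrites)
                if not pool:
                    raise PlacementError(
                        "no "
                        + ("aspiny" if target_class == "aspiny_shaft"
                           else "spiny")
                        + " dendrite available for requested target mix")
                dend = pool[rng.integers(len(pool))]
                u0 = rng.uniform(margin, ext[0] - margin)
                phi0 = rng.uniform(0, 2 * np.pi)
                a_u, a_v, rshape = _patch_semiaxes(
                    area, shape, dend.radius * 1.05, _SHAFT_PATCH_UMAX)
                rad = np.cos(phi0) * dend.b1 + np.sin(phi0) * dend.b2
                mid = (dend.p0 + u0 * dend.direction
                       + (dend.radius + 0.5 * t) * rad)
                probes = np.array([mid,
                                   mid + 0.7 * a_u * dend.direction,
                                   mid - 0.7 * a_u * dend.direction])
                if canvas.probe_blocked(probes, dend.object_id):
                    continue
                sid = next_id
                n_vox = place_cyl_junction(
                    dend.p0, dend.direction, dend.b1, dend.b2,
                    dend.radius, u0, phi0, t, a_u, a_v,
                    _SHAPE_CODE[rshape], w0, dend.object_id, sid)
                if n_vox is None:
                    continue
                sid = new_object(SYNAPSE)
                truths.append(SynapseTruth(
                    sid, syn_type, rshape, target_class, dend.object_id,
                    dend.object_id, None, None, t, n_vox,
                    n_vox * voxvol / t))
                placed = True
                break

            if not spiny_dendrites:
                raise PlacementError(
                    "no spiny dendrite available for spine-targeting mix")

            if target_class == "spine_head":
                reuse = (heads and
                         rng.random() < config.multi_synapse_head_fraction)
                if reuse:
                    head = heads[rng.integers(len(heads))]
                    # second junction off-pole, away from the neck
                    hb1, hb2 = _perp_basis(head.pole)
                    ang = rng.uniform(0, 2 * np.pi)
                    tilt = np.deg2rad(75)
                    pole = _unit(np.cos(tilt) * head.pole
                                 + np.sin(tilt) * (np.cos(ang) * hb1
                                                   + np.sin(ang) * hb2))
                else:
                    dend = spiny_dendrites[rng.integers(len(spiny_dendrites))]
                    head = _try_build_spine(dend, spine_scale)
                    if head is None:
                        continue
                    pole = head.pole
                cap_lim = head.radius * 1.35
                a_u, a_v, rshape = _patch_semiaxes(area, shape,
                                                   cap_lim, cap_lim)
                m1, m2 = _perp_basis(pole)
                r_ext = head.radius + t + 30.0
                b = canvas.bounds(head.center - r_ext, head.center + r_ext)
                ok = b is not None
                if ok:
                    n_vox = K.sphere_patch(
                        labels, *b, dx, dy, dz, head.center, head.radius,
                        pole, m1, m2, t, a_u, a_v, _SHAPE_CODE[rshape],
                        w0, head.object_id, 0, False)
                    ok = n_vox >= 0
                if ok:
                    sid = next_id
                    n_vox = K.sphere_patch(
                        labels, *b, dx, dy, dz, head.center, head.radius,
                        pole, m1, m2, t, a_u, a_v, _SHAPE_CODE[rshape],
                        w0, head.object_id, sid, True)
                    if n_vox < _MIN_JUNCTION_VOXELS:
                        canvas.erase(b, sid)
                        ok = False
                if not ok:
                    if not reuse:
                        rollback_spine(head)
                    continue
                sid = new_object(SYNAPSE)
                head.n_synapses += 1
                truths.append(SynapseTruth(
                    sid, syn_type, rshape, target_class, head.object_id,
                    head.parent_id, head.object_id, head.neck_id, t, n_vox,
                    n_vox * voxvol / t))
                placed = True
                break

            # spine_neck target
            dend = spiny_dendrites[rng.integers(len(spiny_dendrites))]
            head = _try_build_spine(dend, spine_scale)
            if head is None:
                continue
            # neck axis runs from the head base downward along -pole;
            # anchor the junction partway down the (minimum) neck length
            neck_top = head.center - (0.75 * head.radius) * head.pole
            down = -head.pole
            nb1, nb2 = _perp_basis(down)
            u_mid = rng.uniform(0.35, 0.6) * _NECK_LENGTH[0]
            phi0 = rng.uniform(0, 2 * np.pi)
            a_u, a_v, rshape = _patch_semiaxes(
                area, shape, _NECK_RADIUS * 1.05, 0.35 * _NECK_LENGTH[0])
            sid = next_id
            n_vox = place_cyl_junction(
                neck_top, down, nb1, nb2, _NECK_RADIUS, u_mid, phi0,
                t, a_u, a_v, _SHAPE_CODE[rshape], w0, head.neck_id, sid)
            if n_vox is None:
                rollback_spine(head)
                continue
            sid = new_object(SYNAPSE)
            truths.append(SynapseTruth(
                sid, syn_type, rshape, target_class, head.neck_id,
                head.parent_id, head.object_id, head.neck_id, t, n_vox,
                n_vox * voxvol / t))
            placed = True
            break

        if not placed:
            raise PlacementError(
                f"could not place synapse {k} ({syn_type} on {target_class}) "
                f"after {config.max_retries} retries; requested density "
                "too high for this volume")

    vol = LabeledVolume(canvas.labels, tuple(canvas.vsize), objects)
    present = set(vol.present_ids())
    trunc = {oid: vol.touches_border(oid) for oid in present}
    for s in truths:
        s.truncated = trunc.get(s.synapse_id, False)
        chain = [s.synapse_id]
        if s.target_class in ("spine_head", "spine_neck"):
            chain += [s.head_id, s.neck_id]
        s.chain_truncated = any(trunc.get(o, True) for o in chain if o)
    truth = SceneGroundTruth(
        synapses=truths,
        dendrite_spiny={dd.object_id: dd.spiny for dd in dendrites},
        object_truncated=trunc,
        config=config,
        spine_parent=spine_parent,
    )
    return vol, truth
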