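"""Numba voxelisation kernels for the scene generator.

Each kernel walks a bounding sub-grid of the label volume once, with
per-voxel early rejection, and either *checks* a candidate object for
overlap with foreign labels or *paints* it into background voxels.
Keeping these as compiled scalar loops (instead of broadcast numpy
passes) is what makes thousand-synapse scenes cheap to generate.

Shape footprints are evaluated in normalised chart coordinates
(U, V) on the unit disk; codes: 0 macular, 1 perforated, 2 horseshoe,
3 fragmented.  The footprint constants must match the taxonomy used by
the scene generator.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# chart footprint constants (normalised unit-disk coordinates); keep in
# sync with sasmorph.synthetic.scene
HOLE_FRAC = 0.42
WEDGE_HALF_RAD = np.deg2rad(40.0)
WEDGE_INNER = 0.30
FRAG_OFFSET = 0.50
FRAG_RADIUS = 0.42

MACULAR_CODE = 0
PERFORATED_CODE = 1
HORSESHOE_CODE = 2
FRAGMENTED_CODE = 3


@njit(cache=True, fastmath=True)
def _footprint(U, V, code, w0):
    rr2 = U * U + V * V
    if rr2 > 1.0:
        return False
    if code == 0:
        return True
    cw = np.cos(w0)
    sw = np.sin(w0)
    Ur = U * cw + V * sw
    Vr = -U * sw + V * cw
    if code == 1:
        return rr2 >= HOLE_FRAC * HOLE_FRAC
    if code == 2:
        ang = abs(np.arctan2(Vr, Ur))
        if ang <= WEDGE_HALF_RAD and rr2 >= WEDGE_INNER * WEDGE_INNER:
            return False
        return True
    du = Ur - FRAG_OFFSET
    if du * du + Vr * Vr <= FRAG_RADIUS * FRAG_RADIUS:
        return True
    du = Ur + FRAG_OFFSET
    return du * du + Vr * Vr <= FRAG_RADIUS * FRAG_RADIUS


@njit(cache=True, fastmath=True)
def cylinder_patch(labels, ix0, ix1, iy0, iy1, iz0, iz1,
                   dx, dy, dz,
                   p0, dvec, b1, b2, r0, u0, phi0, t,
                   a_u, a_v, code, w0,
                   allowed, paint_id, do_paint):
    """Shell patch on a cylinder surface; check or paint in one pass.

    Returns the number of voxels (painted, or members when checking);
    -1 signals a conflict with a foreign object during a check pass.
    """
    count = 0
    rmax2 = (r0 + t) * (r0 + t)
    r02 = r0 * r0
    for iz in range(iz0, iz1):
        z = (iz + 0.5) * dz - p0[2]
        for iy in range(iy0, iy1):
            y = (iy + 0.5) * dy - p0[1]
            for ix in range(ix0, ix1):
                x = (ix + 0.5) * dx - p0[0]
                ax = x * dvec[0] + y * dvec[1] + z * dvec[2]
                du = ax - u0
                if du > a_u or du < -a_u:
                    continue
                rx = x - ax * dvec[0]
                ry = y - ax * dvec[1]
                rz = z - ax * dvec[2]
                rho2 = rx * rx + ry * ry + rz * rz
                if rho2 < r02 or rho2 >= rmax2:
                    continue
                c1 = rx * b1[0] + ry * b1[1] + rz * b1[2]
                c2 = rx * b2[0] + ry * b2[1] + rz * b2[2]
                phi = np.arctan2(c2, c1)
                dphi = phi - phi0
                if dphi > np.pi:
                    dphi -= 2 * np.pi
                elif dphi < -np.pi:
                    dphi += 2 * np.pi
                if not _footprint(du / a_u, dphi * r0 / a_v, code, w0):
                    continue
                lab = labels[iz, iy, ix]
                if do_paint:
                    if lab == 0:
                        labels[iz, iy, ix] = paint_id
                        count += 1
                else:
                    if lab != 0 and lab != allowed:
                        return -1
                    count += 1
    return count


@njit(cache=True, fastmath=True)
def sphere_patch(labels, ix0, ix1, iy0, iy1, iz0, iz1,
                 dx, dy, dz,
                 c, R, m, m1, m2, t,
                 a_u, a_v, code, w0,
                 allowed, paint_id, do_paint):
    """Shell patch on a sphere around pole direction m."""
    count = 0
    rmax2 = (R + t) * (R + t)
    r02 = R * R
    for iz in range(iz0, iz1):
        z = (iz + 0.5) * dz - c[2]
        for iy in range(iy0, iy1):
            y = (iy + 0.5) * dy - c[1]
            for ix in range(ix0, ix1):
                x = (ix + 0.5) * dx - c[0]
                rho2 = x * x + y * y + z * z
                if rho2 < r02 or rho2 >= rmax2:
                    continue
                rho = np.sqrt(rho2)
                ux = x / rho
                uy = y / rho
                uz = z / rho
                cosb = ux * m[0] + uy * m[1] + uz * m[2]
                if cosb > 1.0:
                    cosb = 1.0
                elif cosb < -1.0:
                    cosb = -1.0
                theta = np.arccos(cosb)
                c1 = ux * m1[0] + uy * m1[1] + uz * m1[2]
                c2 = ux * m2[0] + uy * m2[1] + uz * m2[2]
                psi = np.arctan2(c2, c1)
                U = (R * theta * np.cos(psi)) / a_u
                V = (R * theta * np.sin(psi)) / a_v
                if not _footprint(U, V, code, w0):
                    continue
                lab = labels[iz, iy, ix]
                if do_paint:
                    if lab == 0:
                        labels[iz, iy, ix] = paint_id
                        count += 1
                else:
                    if lab != 0 and lab != allowed:
                        return -1
                    count += 1
    return count


@njit(cache=True, fastmath=True)
def capsule(labels, ix0, ix1, iy0, iy1, iz0, iz1,
            dx, dy, dz,
            p0, p1, r,
            allowed1, allowed2, paint_id, do_paint):
    """Capsule (cylinder with spherical caps) between two points."""
    count = 0
    sx = p1[0] - p0[0]
    sy = p1[1] - p0[1]
    sz = p1[2] - p0[2]
    L2 = sx * sx + sy * sy + sz * sz
    r2 = r * r
    for iz in range(iz0, iz1):
        z = (iz + 0.5) * dz - p0[2]
        for iy in range(iy0, iy1):
            y = (iy + 0.5) * dy - p0[1]
            for ix in range(ix0, ix1):
                x = (ix + 0.5) * dx - p0[0]
                tt = 0.0
                if L2 > 0:
                    tt = (x * sx + y * sy + z * sz) / L2
                    if tt < 0.0:
                        tt = 0.0
                    elif tt > 1.0:
                        tt = 1.0
                ex = x - tt * sx
                ey = y - tt * sy
                ez = z - tt * sz
                if ex * ex + ey * ey + ez * ez > r2:
                    continue
                lab = labels[iz, iy, ix]
                if do_paint:
                    if lab == 0:
                        labels[iz, iy, ix] = paint_id
                        count += 1
                else:
                    if lab != 0 and lab != allowed1 and lab != allowed2:
                        return -1
                    count += 1
    return count
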