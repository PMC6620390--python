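"""Labeled anisotropic voxel volumes of synthetic neuropil.

A :class:`LabeledVolume` is a dense uint16 grid of per-voxel object IDs
(0 = background) plus an object table mapping each ID to its semantic
class.  Axis order of the array is ``(z, y, x)`` (the FIB/SEM convention:
pages are serial sections); voxel size is given per spatial axis as
``(dx, dy, dz)`` in nm, default 5 x 5 x 20 nm (5 nm/pixel in-plane,
20 nm section thickness).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# semantic classes of labeled objects
DENDRITIC_SHAFT = "dendritic_shaft"
SPINE_NECK = "spine_neck"
SPINE_HEAD = "spine_head"
SYNAPSE = "synapse"

SEMANTIC_CLASSES = (DENDRITIC_SHAFT, SPINE_NECK, SPINE_HEAD, SYNAPSE)


@dataclass
class ObjectInfo:
    """One labeled object: its ID and semantic class."""

    object_id: int
    semantic: str

    def __post_init__(self) -> None:
        if self.semantic not in SEMANTIC_CLASSES:
            raise ValueError(f"unknown semantic class {self.semantic!r}")


class UnknownObjectError(KeyError):
    """Lookup of an object ID absent from the volume."""


@dataclass
class LabeledVolume:
    """Dense label grid with per-object semantics.

    Parameters
    ----------
    labels : (nz, ny, nx) uint16 array
        Per-voxel object IDs; 0 is background.
    voxel_size_nm : (dx, dy, dz)
        Voxel pitch in nm along x, y, z.
    objects : dict[int, ObjectInfo]
        Object table; every nonzero label in ``labels`` must appear here.
    """

    labels: np.ndarray
    voxel_size_nm: tuple[float, float, float]
    objects: dict[int, ObjectInfo] = field(default_factory=dict)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D (z, y, x) array")
        self.voxel_size_nm = tuple(float(v) for v in self.voxel_size_nm)
        if len(self.voxel_size_nm) != 3 or min(self.voxel_size_nm) <= 0:
            raise ValueError("voxel_size_nm must be three positive values")

    # -- geometry helpers -------------------------------------------------

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) in nm."""
        nz, ny, nx = self.labels.shape
        dx, dy, dz = self.voxel_size_nm
        return (nx * dx, ny * dy, nz * dz)

    @property
    def volume_um3(self) -> float:
        ex, ey, ez = self.extent_nm
        return ex * ey * ez * 1e-9

    def voxel_indices(self, object_id: int) -> np.ndarray:
        """(k, 3) array of (z, y, x) voxel indices of an object."""
        idx = self._object_index().get(int(object_id))
        if idx is None:
            raise UnknownObjectError(
                f"object {object_id} not present in volume"
            )
        return np.column_stack(np.unravel_index(idx, self.labels.shape))

    def _object_index(self) -> dict[int, np.ndarray]:
        """Flat voxel indices per object, built once.

        Only nonzero voxels are sorted, which keeps the cost proportional
        to the foreground (a few percent of a neuropil stack).
        """
        if "obj_index" not in self._cache:
            flat = self.labels.ravel()
            nz = np.flatnonzero(flat)
            labs = flat[nz]
            order = np.argsort(labs, kind="stable")
            nz = nz[order]
            labs = labs[order]
            uniq, starts = np.unique(labs, return_index=True)
            bounds = list(starts) + [len(labs)]
            index = {
                int(lab): nz[bounds[i]:bounds[i + 1]]
                for i, lab in enumerate(uniq)
            }
            self._cache["obj_index"] = index
        return self._cache["obj_index"]

    def present_ids(self) -> list[int]:
        return sorted(self._object_index().keys())

    def voxel_centers_nm(self, object_id: int) -> np.ndarray:
        """(k, 3) voxel center coordinates in nm, columns (x, y, z)."""
        zyx = self.voxel_indices(object_id)
        dx, dy, dz = self.voxel_size_nm
        return np.column_stack([
            (zyx[:, 2] + 0.5) * dx,
            (zyx[:, 1] + 0.5) * dy,
            (zyx[:, 0] + 0.5) * dz,
        ])

    def touches_border(self, object_id: int) -> bool:
        """True iff the object's voxel set intersects a volume face."""
        zyx = self.voxel_indices(object_id)
        nz, ny, nx = self.labels.shape
        return bool(
            np.any(zyx == 0)
            or np.any(zyx[:, 0] == nz - 1)
            or np.any(zyx[:, 1] == ny - 1)
            or np.any(zyx[:, 2] == nx - 1)
        )

    def semantic_of(self, object_id: int) -> str:
        info = self.objects.get(int(object_id))
        if info is None:
            raise UnknownObjectError(f"object {object_id} not in object table")
        return info.semantic

    def ids_of_class(self, semantic: str) -> list[int]:
        return sorted(
            oid for oid, info in self.objects.items()
            if info.semantic == semantic and oid in self._object_index()
        )

    # -- contact areas ----------------------------------------------------

    def contact_areas(self) -> dict[tuple[int, int], float]:
        """Shared face area (nm^2) between every pair of touching objects.

        Keys are ``(a, b)`` with ``a < b``; a pair is present only if the
        two objects share at least one voxel face.
        """
        if "contacts" in self._cache:
            return self._cache["contacts"]
        dx, dy, dz = self.voxel_size_nm
        face_area = {0: dx * dy, 1: dx * dz, 2: dy * dz}  # z-, y-, x-normal
        lab = self.labels
        contacts: dict[tuple[int, int], float] = {}
        for axis, area in face_area.items():
            sl1 = [slice(None)] * 3
            sl2 = [slice(None)] * 3
            sl1[axis] = slice(None, -1)
            sl2[axis] = slice(1, None)
            a = lab[tuple(sl1)]
            b = lab[tuple(sl2)]
            mask = (a != b) & (a > 0) & (b > 0)
            if not mask.any():
                continue
            pa = a[mask].astype(np.int64)
            pb = b[mask].astype(np.int64)
            lo = np.minimum(pa, pb)
            hi = np.maximum(pa, pb)
            keys = lo * (2 ** 20) + hi
            uniq, counts = np.unique(keys, return_counts=True)
            for k, c in zip(uniq, counts):
                pair = (int(k >> 20), int(k & (2 ** 20 - 1)))
                contacts[pair] = contacts.get(pair, 0.0) + float(c) * area
        self._cache["contacts"] = contacts
        return contacts

    def invalidate_caches(self) -> None:
        self._cache.clear()
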