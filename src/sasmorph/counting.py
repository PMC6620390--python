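"""Unbiased 3D counting frame (CF) for direct synapse counting.

The CF is a rectangular prism bounded by three *acceptance* faces (at
the axis minima, by this package's convention) and three *exclusion*
faces (at the maxima).  Objects intersecting any exclusion face are
never counted; objects lying inside the frame or intersecting only
acceptance faces are counted.  Faces are finite rectangles (no infinite
plane extensions), and exclusion is tested first, which makes a tiling
of frames count each convex interior object exactly once.

Objects are voxel sets; each voxel is treated as its closed axis-aligned
nm box, so "intersecting a face" includes exact touching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import SYNAPSE, LabeledVolume

COUNTED = "counted"
NOT_COUNTED = "not_counted"


@dataclass(frozen=True)
class CountingFrame:
    """Axis-aligned counting frame in nm, (x, y, z) order."""

    min_nm: tuple[float, float, float]
    max_nm: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo = np.asarray(self.min_nm, float)
        hi = np.asarray(self.max_nm, float)
        if lo.shape != (3,) or hi.shape != (3,) or np.any(lo >= hi):
            raise ValueError("frame needs min < max on every axis")

    @property
    def volume_um3(self) -> float:
        lo = np.asarray(self.min_nm)
        hi = np.asarray(self.max_nm)
        return float(np.prod(hi - lo)) * 1e-9

    @classmethod
    def from_margins(cls, vol: LabeledVolume,
                     margin_nm: float | tuple[float, float, float]
                     ) -> "CountingFrame":
        """Frame inset from the volume borders by a nm margin per axis."""
        m = np.broadcast_to(np.asarray(margin_nm, float), (3,))
        ext = np.asarray(vol.extent_nm)
        return cls(tuple(m), tuple(ext - m))


def _voxel_boxes(centers_nm: np.ndarray,
                 voxel_size_nm: tuple[float, float, float]
                 ) -> tuple[np.ndarray, np.ndarray]:
    half = np.asarray(voxel_size_nm, float) / 2.0
    c = np.asarray(centers_nm, float)
    return c - half, c + half


def cf_decision(centers_nm: np.ndarray,
                voxel_size_nm: tuple[float, float, float],
                frame: CountingFrame) -> str:
    """Counting decision for one object given its voxel centers (nm).

    Returns ``"counted"`` or ``"not_counted"``; raises on an empty
    object.
    """
    c = np.asarray(centers_nm, float).reshape(-1, 3)
    if len(c) == 0:
        raise ValueError("empty object has no counting decision")
    lo, hi = _voxel_boxes(c, voxel_size_nm)
    fmin = np.asarray(frame.min_nm)
    fmax = np.asarray(frame.max_nm)

    # overlap of a box with the frame's cross-section on the other axes
    def face_overlap(axis: int) -> np.ndarray:
        others = [a for a in range(3) if a != axis]
        ok = np.ones(len(c), dtype=bool)
        for a in others:
            ok &= (lo[:, a] <= fmax[a]) & (hi[:, a] >= fmin[a])
        return ok

    # exclusion faces: plane at the axis maximum
    for axis in range(3):
        touches = (lo[:, axis] <= fmax[axis]) & (hi[:, axis] >= fmax[axis])
        if np.any(touches & face_overlap(axis)):
            return NOT_COUNTED
    # acceptance faces: plane at the axis minimum
    for axis in range(3):
        touches = (lo[:, axis] <= fmin[axis]) & (hi[:, axis] >= fmin[axis])
        if np.any(touches & face_overlap(axis)):
            return COUNTED
    # strict interior
    inside = np.all((hi > fmin) & (lo < fmax), axis=1)
    return COUNTED if np.any(inside) else NOT_COUNTED


def count_in_frame(vol: LabeledVolume, frame: CountingFrame,
                   annotations: pd.DataFrame | None = None,
                   by: list[str] | None = None) -> pd.Series | pd.DataFrame:
    """Synapse counts inside the frame, optionally grouped by annotation.

    ``annotations`` is a per-synapse table indexed by synapse_id (e.g.
    with ``type`` / ``shape`` / ``target`` columns); ``by`` selects the
    grouping columns.  Without annotations a single total is returned as
    a one-element Series.  Raises if the frame exceeds the volume.
    """
    ext = np.asarray(vol.extent_nm)
    if (np.any(np.asarray(frame.min_nm) < 0)
            or np.any(np.asarray(frame.max_nm) > ext + 1e-9)):
        raise ValueError("counting frame exceeds the volume bounds")
    decisions = {}
    for sid in vol.ids_of_class(SYNAPSE):
        decisions[sid] = cf_decision(
            vol.voxel_centers_nm(sid), vol.voxel_size_nm, frame)
    counted_ids = [s for s, d in decisions.items() if d == COUNTED]
    if annotations is None or not by:
        return pd.Series({"synapses": len(counted_ids)})
    sub = annotations.loc[annotations.index.intersection(counted_ids)]
    return sub.groupby(by, observed=False).size()
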