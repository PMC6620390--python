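"""Fixture serialisation: multipage TIFF label stacks with JSON sidecars.

A fixture directory holds ``labels.tif`` (uint16 object IDs, one page
per section), ``sidecar.json`` (voxel size, semantic map, object table,
generator seed) and, when ground truth is available, ``truth.json``.
Round-trips are lossless.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile

from ..volume import LabeledVolume, ObjectInfo
from .config import ScenarioConfig
from .scene import SceneGroundTruth, SynapseTruth

LABELS_NAME = "labels.tif"
SIDECAR_NAME = "sidecar.json"
TRUTH_NAME = "truth.json"


def write_fixture(vol: LabeledVolume, truth: SceneGroundTruth | None,
                  path: str | Path) -> Path:
    """Serialise a labeled volume (and optional truth) to a directory."""
    out = Path(path)
    try:
        out.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out / LABELS_NAME, vol.labels.astype(np.uint16))
        sidecar = {
            "voxel_size_nm": list(vol.voxel_size_nm),
            "semantic_map": {str(oid): info.semantic
                             for oid, info in sorted(vol.objects.items())},
            "objects": [
                {
                    "object_id": oid,
                    "semantic": info.semantic,
                    "truncated": (truth.object_truncated.get(oid)
                                  if truth else None),
                }
                for oid, info in sorted(vol.objects.items())
            ],
            "seed": truth.config.seed if truth else None,
        }
        (out / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
        if truth is not None:
            payload = {
                "config": truth.config.to_dict(),
                "synapses": [asdict(s) for s in truth.synapses],
                "dendrite_spiny": {str(k): bool(v)
                                   for k, v in truth.dendrite_spiny.items()},
                "object_truncated": {str(k): bool(v)
                                     for k, v in truth.object_truncated.items()},
                "spine_parent": {str(k): int(v)
                                 for k, v in truth.spine_parent.items()},
            }
            (out / TRUTH_NAME).write_text(json.dumps(payload, indent=1))
    except OSError as exc:
        raise OSError(f"failed to write fixture at {out}: {exc}") from exc
    return out


def read_fixture(path: str | Path) -> tuple[LabeledVolume,
                                            SceneGroundTruth | None]:
    """Load a fixture directory back into memory."""
    src = Path(path)
    try:
        labels = tifffile.imread(src / LABELS_NAME)
        sidecar = json.loads((src / SIDECAR_NAME).read_text())
    except OSError as exc:
        raise OSError(f"failed to read fixture at {src}: {exc}") from exc
    objects = {
        int(oid): ObjectInfo(int(oid), sem)
        for oid, sem in sidecar["semantic_map"].items()
    }
    vol = LabeledVolume(labels, tuple(sidecar["voxel_size_nm"]), objects)
    truth = None
    truth_file = src / TRUTH_NAME
    if truth_file.exists():
        payload = json.loads(truth_file.read_text())
        truth = SceneGroundTruth(
            synapses=[SynapseTruth(**s) for s in payload["synapses"]],
            dendrite_spiny={int(k): v
                            for k, v in payload["dendrite_spiny"].items()},
            object_truncated={int(k): v
                              for k, v in payload["object_truncated"].items()},
            config=ScenarioConfig.from_dict(payload["config"]),
            spine_parent={int(k): v
                          for k, v in payload.get("spine_parent", {}).items()},
        )
    return vol, truth
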