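"""Postsynaptic target assignment and spine-head occupancy.

The postsynaptic element of a junction is the labeled object sharing the
largest voxel-face contact area with it (ties broken by lowest object
ID).  Spine targets must be *traceable*: a head must connect, through a
neck, to a dendritic shaft within the volume; a neck must connect to a
shaft.  When tracing fails because the spine is cut by the stack border
the synapse is labeled ``unknown`` — the same rule the source 3D EM
protocol applied to truncated elements.  Shaft targets are subdivided by
the spininess of the target dendrite, judged purely from what is inside
the volume (a dendrite is spiny iff at least one spine neck is attached
to it in the stack).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx

from .volume import (DENDRITIC_SHAFT, SPINE_HEAD, SPINE_NECK, SYNAPSE,
                     LabeledVolume)

SPINE_HEAD_T = "spine_head"
SPINE_NECK_T = "spine_neck"
ASPINY_SHAFT_T = "aspiny_shaft"
SPINY_SHAFT_T = "spiny_shaft"
UNKNOWN_T = "unknown"

TARGET_CLASSES = (SPINE_HEAD_T, SPINE_NECK_T, ASPINY_SHAFT_T, SPINY_SHAFT_T)


class MalformedSceneError(RuntimeError):
    """A junction with no postsynaptic contact, or an untraceable spine
    that does not touch the stack border."""


@dataclass(frozen=True)
class TargetCall:
    """Target classification of one synapse."""

    synapse_id: int
    target_class: str
    postsynaptic_object_id: int | None
    traced_to_parent: bool


def object_graph(vol: LabeledVolume) -> nx.Graph:
    """Adjacency graph of labeled objects (edges weighted by contact nm^2)."""
    g = nx.Graph()
    for oid in vol.present_ids():
        g.add_node(oid, semantic=vol.semantic_of(oid))
    for (a, b), area in vol.contact_areas().items():
        g.add_edge(a, b, area=area)
    return g


def _is_spiny(vol: LabeledVolume, graph: nx.Graph, shaft_id: int) -> bool:
    return any(vol.semantic_of(nb) == SPINE_NECK
               for nb in graph.neighbors(shaft_id))


def assign_target(vol: LabeledVolume, synapse_id: int,
                  graph: nx.Graph | None = None) -> TargetCall:
    """Classify the postsynaptic target of one junction."""
    if graph is None:
        graph = object_graph(vol)
    if vol.semantic_of(synapse_id) != SYNAPSE:
        raise ValueError(f"object {synapse_id} is not a synapse")
    candidates = [
        (nb, graph.edges[synapse_id, nb]["area"])
        for nb in graph.neighbors(synapse_id)
        if vol.semantic_of(nb) != SYNAPSE
    ]
    if not candidates:
        raise MalformedSceneError(
            f"synapse {synapse_id} has no postsynaptic contact")
    # largest contact area; ties -> lowest object ID (deterministic)
    candidates.sort(key=lambda t: (-t[1], t[0]))
    post_id = candidates[0][0]
    semantic = vol.semantic_of(post_id)

    if semantic == DENDRITIC_SHAFT:
        cls = (SPINY_SHAFT_T if _is_spiny(vol, graph, post_id)
               else ASPINY_SHAFT_T)
        return TargetCall(synapse_id, cls, post_id, traced_to_parent=False)

    if semantic == SPINE_HEAD:
        necks = [nb for nb in graph.neighbors(post_id)
                 if vol.semantic_of(nb) == SPINE_NECK]
        for neck in necks:
            if any(vol.semantic_of(nb) == DENDRITIC_SHAFT
                   for nb in graph.neighbors(neck)):
                return TargetCall(synapse_id, SPINE_HEAD_T, post_id, True)
        chain = [post_id] + necks
        if any(vol.touches_border(o) for o in chain):
            return TargetCall(synapse_id, UNKNOWN_T, post_id, False)
        raise MalformedSceneError(
            f"spine head {post_id} cannot be traced to a dendrite and does "
            "not touch the stack border")

    if semantic == SPINE_NECK:
        if any(vol.semantic_of(nb) == DENDRITIC_SHAFT
               for nb in graph.neighbors(post_id)):
            return TargetCall(synapse_id, SPINE_NECK_T, post_id, True)
        if vol.touches_border(post_id):
            return TargetCall(synapse_id, UNKNOWN_T, post_id, False)
        raise MalformedSceneError(
            f"spine neck {post_id} cannot be traced to a dendrite and does "
            "not touch the stack border")

    raise MalformedSceneError(
        f"synapse {synapse_id} apposed to unexpected class {semantic}")


def assign_all_targets(vol: LabeledVolume) -> dict[int, TargetCall]:
    """Target calls for every synapse object in the volume."""
    graph = object_graph(vol)
    return {
        sid: assign_target(vol, sid, graph)
        for sid in vol.ids_of_class(SYNAPSE)
    }


@dataclass(frozen=True)
class SpineOccupancy:
    """Synapse composition of one spine head."""

    spine_head_id: int
    composition: tuple[str, ...]  # sorted AS/SS multiset


#: occupancy bins reported in the frequency table
OCCUPANCY_BINS = ("1AS", "1SS", "2AS", "AS+SS", "2AS+1SS", "other")


def _bin_of(comp: tuple[str, ...]) -> str:
    c = Counter(comp)
    key = (c.get("AS", 0), c.get("SS", 0))
    return {
        (1, 0): "1AS", (0, 1): "1SS", (2, 0): "2AS",
        (1, 1): "AS+SS", (2, 1): "2AS+1SS",
    }.get(key, "other")


def spine_occupancy(calls: dict[int, TargetCall],
                    types: dict[int, str]) -> tuple[list[SpineOccupancy],
                                                    dict[str, float]]:
    """Per-head synapse composition and its frequency table.

    ``types`` maps synapse_id -> "AS"/"SS".  Frequencies are percentages
    of occupied spine heads and sum to 100 (up to float rounding).
    """
    per_head: dict[int, list[str]] = {}
    for call in calls.values():
        if call.target_class == SPINE_HEAD_T:
            per_head.setdefault(call.postsynaptic_object_id, []).append(
                types[call.synapse_id])
    occ = [SpineOccupancy(h, tuple(sorted(comp)))
           for h, comp in sorted(per_head.items())]
    counts = Counter(_bin_of(o.composition) for o in occ)
    total = sum(counts.values())
    freq = {b: (100.0 * counts.get(b, 0) / total if total else 0.0)
            for b in OCCUPANCY_BINS}
    return occ, freq
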