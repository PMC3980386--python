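"""Tracing cavities through time: the time graph, identities, and dynamic paths.

Cavities of consecutive frames *correspond* when some empty sphere of one and
some empty sphere of the other intersect with an inscribed intersection-circle
radius greater than a minimal radius r_ic (which should equal or resemble the
probe radius). Correspondences form an undirected *time graph* whose nodes are
(frame, cavity) pairs; splits and merges appear as nodes with several edges
to the next or previous frame.

Stable identification numbers are assigned per frame transition by a greedy
matching: edges sorted by intersection volume, largest first; an edge is
matched only if both endpoints are still unmatched; matched nodes inherit the
identity, unmatched ones get fresh numbers. Dead ends can be removed
(truncated back to the nearest split) and splits can be forbidden (keeping
only matched continuations, so each identity is a simple chain). A dynamic
cavity is a path through the time graph visiting user-selected nodes, found
by depth-first search that prefers larger intersection volumes.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .cavity_model import Cavity
from .config import DEFAULT_CUBE_LENGTH, DEFAULT_MIN_INTERSECTION_RADIUS
from .volumetrics import (
    cavity_intersection_volume,
    cavity_volume,
    intersection_circle_radii,
)

NodeKey = Tuple[int, int]  # (frame_index, cavity_id)


@dataclasses.dataclass
class TimeEdge:
    """Correspondence between cavity ``cavity_t`` at frame ``frame_t`` and
    ``cavity_t1`` at frame ``frame_t + 1``."""

    frame_t: int
    cavity_t: int
    cavity_t1: int
    circle_radius: float
    intersection_volume: float

    @property
    def node_t(self) -> NodeKey:
        return (self.frame_t, self.cavity_t)

    @property
    def node_t1(self) -> NodeKey:
        return (self.frame_t + 1, self.cavity_t1)


@dataclasses.dataclass
class TimeGraph:
    """Per-frame cavity nodes with inter-frame correspondence edges."""

    frames: List[int]  # traced frame indices, consecutive and increasing
    nodes: Dict[NodeKey, dict]  # key -> {"volume": float, "identity": int|None}
    edges: List[TimeEdge]

    def forward_edges(self, key: NodeKey) -> List[TimeEdge]:
        return [e for e in self.edges if e.node_t == key]

    def backward_edges(self, key: NodeKey) -> List[TimeEdge]:
        return [e for e in self.edges if e.node_t1 == key]

    def nodes_at(self, frame: int) -> List[NodeKey]:
        return sorted(k for k in self.nodes if k[0] == frame)

    def identity(self, key: NodeKey) -> Optional[int]:
        return self.nodes[key].get("identity")

    def copy(self) -> "TimeGraph":
        return TimeGraph(
            frames=list(self.frames),
            nodes=copy.deepcopy(self.nodes),
            edges=[dataclasses.replace(e) for e in self.edges],
        )


@dataclasses.dataclass
class DynamicCavity:
    """A chain of time-graph nodes, one per traversed frame."""

    nodes: List[NodeKey]

    def __post_init__(self) -> None:
        for a, b in zip(self.nodes, self.nodes[1:]):
            if b[0] != a[0] + 1:
                raise ValueError("dynamic cavity nodes must advance one frame per step")


# ---------------------------------------------------------------------------
# Correspondence
# ---------------------------------------------------------------------------

def max_intersection_circle(c1: Cavity, c2: Cavity) -> float:
    """Largest inscribed intersection-circle radius over all sphere pairs.

    Sphere pairs are pruned with a KD-tree on center distances; the result
    equals the brute-force all-pairs maximum (pruned pairs are disjoint).
    Returns -inf when no spheres intersect.
    """
    if c1.n_spheres == 0 or c2.n_spheres == 0:
        return float("-inf")
    tree = cKDTree(c2.centers)
    max_r2 = float(c2.radii.max())
    best = float("-inf")
    for i in range(c1.n_spheres):
        cand = tree.query_ball_point(c1.centers[i], float(c1.radii[i]) + max_r2)
        if not cand:
            continue
        radii = intersection_circle_radii(
            c1.centers[i : i + 1], c1.radii[i : i + 1], c2.centers[cand], c2.radii[cand]
        )
        if radii.size and not np.all(np.isnan(radii)):
            best = max(best, float(np.nanmax(radii)))
    return best


def map_cavities_between_frames(
    cavs_t: Sequence[Cavity],
    cavs_t1: Sequence[Cavity],
    r_ic: float = DEFAULT_MIN_INTERSECTION_RADIUS,
    a: float = DEFAULT_CUBE_LENGTH,
) -> List[TimeEdge]:
    """Correspondence edges between the cavities of two consecutive frames.

    Cavities correspond when their maximal sphere-pair inscribed-circle radius
    is strictly greater than ``r_ic``; each edge also carries the grid
    intersection volume used later as the matching weight.
    """
    edges: List[TimeEdge] = []
    for A in cavs_t:
        for B in cavs_t1:
            lo = np.maximum(A.aabb[0], B.aabb[0])
            hi = np.minimum(A.aabb[1], B.aabb[1])
            if np.any(hi <= lo):
                continue
            circ = max_intersection_circle(A, B)
            if circ > r_ic:
                edges.append(
                    TimeEdge(
                        frame_t=A.frame_index,
                        cavity_t=A.cavity_id,
                        cavity_t1=B.cavity_id,
                        circle_radius=circ,
                        intersection_volume=cavity_intersection_volume(A, B, a),
                    )
                )
    return edges


def build_time_graph(
    cavities_per_frame: Sequence[Sequence[Cavity]],
    r_ic: float = DEFAULT_MIN_INTERSECTION_RADIUS,
    a: float = DEFAULT_CUBE_LENGTH,
) -> TimeGraph:
    """Assemble the time graph of a traced frame range (volumes included)."""
    frames = [cavs[0].frame_index if cavs else None for cavs in cavities_per_frame]
    # Frames may be empty of cavities; infer indices from neighbors.
    known = [f for f in frames if f is not None]
    if known:
        start = known[0] - frames.index(known[0])
        frames = [start + i for i in range(len(cavities_per_frame))]
    else:
        frames = list(range(len(cavities_per_frame)))
    nodes: Dict[NodeKey, dict] = {}
    for f_idx, cavs in zip(frames, cavities_per_frame):
        for cav in cavs:
            nodes[(f_idx, cav.cavity_id)] = {"volume": cavity_volume(cav, a), "identity": None}
    edges: List[TimeEdge] = []
    for cavs_t, cavs_t1 in zip(cavities_per_frame, cavities_per_frame[1:]):
        edges.extend(map_cavities_between_frames(cavs_t, cavs_t1, r_ic=r_ic, a=a))
    return TimeGraph(frames=frames, nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# Identity numbers
# ---------------------------------------------------------------------------

def assign_identity_numbers(tg: TimeGraph) -> TimeGraph:
    """Greedy volume-sorted matching per frame transition.

    First-frame cavities are numbered consecutively in cavity-id order. For
    each transition, edges of the bipartite subgraph are sorted by
    intersection volume (descending; ties by ascending (identity_t,
    cavity_id_t1)) and matched greedily, skipping edges with an already
    matched endpoint. Matched nodes inherit the identity; every unmatched
    node gets a fresh, never-used number.
    """
    if not tg.frames:
        return tg
    next_identity = 0
    for key in tg.nodes_at(tg.frames[0]):
        tg.nodes[key]["identity"] = next_identity
        next_identity += 1
    edges_by_frame: Dict[int, List[TimeEdge]] = {}
    for e in tg.edges:
        edges_by_frame.setdefault(e.frame_t, []).append(e)
    for t in tg.frames[:-1]:
        sub = edges_by_frame.get(t, [])
        sub = sorted(
            sub,
            key=lambda e: (
                -e.intersection_volume,
                tg.nodes[e.node_t]["identity"],
                e.cavity_t1,
            ),
        )
        matched_t: set = set()
        matched_t1: set = set()
        for e in sub:
            if e.node_t in matched_t or e.node_t1 in matched_t1:
                continue
            matched_t.add(e.node_t)
            matched_t1.add(e.node_t1)
            tg.nodes[e.node_t1]["identity"] = tg.nodes[e.node_t]["identity"]
        for key in tg.nodes_at(t + 1):
            if key not in matched_t1:
                tg.nodes[key]["identity"] = next_identity
                next_identity += 1
    return tg


# ---------------------------------------------------------------------------
# Graph editing passes
# ---------------------------------------------------------------------------

def remove_dead_ends(tg: TimeGraph) -> TimeGraph:
    """Remove cavities that fail to continue, traced back to the last split.

    A node with no forward edge to a surviving node (while a later frame
    exists in the traced range) is removed; removal propagates backwards
    along its chain until a node retains at least one other forward edge (a
    split point) or the range start is reached. Final-frame survivors are
    kept (there is no following frame to continue into).
    """
    out = tg.copy()
    if not out.frames:
        return out
    last = out.frames[-1]
    alive = set(out.nodes)
    forward: Dict[NodeKey, List[TimeEdge]] = {}
    for e in out.edges:
        forward.setdefault(e.node_t, []).append(e)
    for t in reversed(out.frames[:-1]):
        for key in out.nodes_at(t):
            if key not in alive:
                continue
            if not any(e.node_t1 in alive for e in forward.get(key, [])):
                alive.discard(key)
    out.nodes = {k: v for k, v in out.nodes.items() if k in alive or k[0] == last}
    out.edges = [
        e for e in out.edges if e.node_t in out.nodes and e.node_t1 in out.nodes
    ]
    return out


def forbid_splits(tg: TimeGraph) -> TimeGraph:
    """Keep only matched continuations so each identity chain is simple.

    Walking forward in time, the greedy matching is recomputed against the
    kept nodes of frame t; unmatched t+1 nodes that are reachable only via
    split edges (i.e. have incoming edges from kept nodes) are dropped, while
    genuinely new cavities (no incoming edges at all) start fresh chains.
    Identities are reassigned on the pruned graph.
    """
    out = tg.copy()
    if not out.frames:
        return out
    kept = set(out.nodes_at(out.frames[0]))
    edges_by_frame: Dict[int, List[TimeEdge]] = {}
    for e in out.edges:
        edges_by_frame.setdefault(e.frame_t, []).append(e)
    dropped: set = set()
    for t in out.frames[:-1]:
        sub = [e for e in edges_by_frame.get(t, []) if e.node_t in kept]
        sub = sorted(sub, key=lambda e: (-e.intersection_volume, e.cavity_t, e.cavity_t1))
        matched_t: set = set()
        matched_t1: set = set()
        for e in sub:
            if e.node_t in matched_t or e.node_t1 in matched_t1:
                continue
            matched_t.add(e.node_t)
            matched_t1.add(e.node_t1)
        has_incoming = {e.node_t1 for e in edges_by_frame.get(t, [])}
        for key in out.nodes_at(t + 1):
            if key in matched_t1:
                kept.add(key)
            elif key in has_incoming:
                dropped.add(key)
            else:
                kept.add(key)  # fresh cavity, starts its own chain
    out.nodes = {k: v for k, v in out.nodes.items() if k not in dropped}
    out.edges = [
        e
        for e in out.edges
        if e.node_t in out.nodes and e.node_t1 in out.nodes
    ]
    # Keep only matching edges so chains are simple paths.
    out.edges = _matching_edges_only(out)
    return assign_identity_numbers(out)


def _matching_edges_only(tg: TimeGraph) -> List[TimeEdge]:
    keep: List[TimeEdge] = []
    edges_by_frame: Dict[int, List[TimeEdge]] = {}
    for e in tg.edges:
        edges_by_frame.setdefault(e.frame_t, []).append(e)
    for t, sub in edges_by_frame.items():
        sub = sorted(sub, key=lambda e: (-e.intersection_volume, e.cavity_t, e.cavity_t1))
        matched_t: set = set()
        matched_t1: set = set()
        for e in sub:
            if e.node_t in matched_t or e.node_t1 in matched_t1:
                continue
            matched_t.add(e.node_t)
            matched_t1.add(e.node_t1)
            keep.append(e)
    return sorted(keep, key=lambda e: (e.frame_t, e.cavity_t, e.cavity_t1))


# ---------------------------------------------------------------------------
# Dynamic paths
# ---------------------------------------------------------------------------

def extract_dynamic_path(
    tg: TimeGraph, selections: Sequence[NodeKey]
) -> Optional[DynamicCavity]:
    """Path through the time graph visiting the selections in frame order.

    Each leg is found by a depth-first search moving forward in time, trying
    larger intersection volumes first. Returns ``None`` when some leg is not
    connected.
    """
    if len(selections) < 2:
        raise ValueError("at least two selections (start and end) are required")
    sels = list(selections)
    if any(b[0] <= a[0] for a, b in zip(sels, sels[1:])):
        raise ValueError("selections must be in strictly increasing frame order")
    for s in sels:
        if s not in tg.nodes:
            raise KeyError(f"selection {s} is not a node of the time graph")

    forward: Dict[NodeKey, List[TimeEdge]] = {}
    for e in tg.edges:
        forward.setdefault(e.node_t, []).append(e)

    full_path: List[NodeKey] = [sels[0]]
    for start, goal in zip(sels, sels[1:]):
        leg = _dfs_leg(start, goal, forward)
        if leg is None:
            return None
        full_path.extend(leg[1:])
    return DynamicCavity(nodes=full_path)


def _dfs_leg(
    start: NodeKey, goal: NodeKey, forward: Dict[NodeKey, List[TimeEdge]]
) -> Optional[List[NodeKey]]:
    stack: List[Tuple[NodeKey, List[NodeKey]]] = [(start, [start])]
    seen: set = set()
    while stack:
        node, path = stack.pop()
        if node == goal:
            return path
        if node in seen or node[0] >= goal[0]:
            continue
        seen.add(node)
        nxt = sorted(
            forward.get(node, []),
            key=lambda e: (e.intersection_volume, -e.cavity_t1),
        )
        # Stack is LIFO: push smaller volumes first so larger are tried first.
        for e in nxt:
            stack.append((e.node_t1, path + [e.node_t1]))
    return None


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def time_graph_to_json_dict(tg: TimeGraph) -> dict:
    return {
        "frames": list(map(int, tg.frames)),
        "nodes": [
            {
                "frame": int(f),
                "cavity_id": int(c),
                "identity": None if v.get("identity") is None else int(v["identity"]),
                "volume": float(v.get("volume", 0.0)),
            }
            for (f, c), v in sorted(tg.nodes.items())
        ],
        "edges": [
            {
                "frame_t": int(e.frame_t),
                "cavity_t": int(e.cavity_t),
                "cavity_t1": int(e.cavity_t1),
                "circle_radius": float(e.circle_radius),
                "intersection_volume": float(e.intersection_volume),
            }
            for e in sorted(tg.edges, key=lambda e: (e.frame_t, e.cavity_t, e.cavity_t1))
        ],
    }


def export_time_graph_json(tg: TimeGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(time_graph_to_json_dict(tg), fh, indent=1)


def time_graph_to_networkx(tg: TimeGraph) -> nx.Graph:
    g = nx.Graph()
    for (f, c), v in sorted(tg.nodes.items()):
        g.add_node(
            f"{f}:{c}",
            frame=int(f),
            cavity_id=int(c),
            identity=-1 if v.get("identity") is None else int(v["identity"]),
            volume=float(v.get("volume", 0.0)),
        )
    for e in tg.edges:
        g.add_edge(
            f"{e.frame_t}:{e.cavity_t}",
            f"{e.frame_t + 1}:{e.cavity_t1}",
            circle_radius=float(e.circle_radius),
            intersection_volume=float(e.intersection_volume),
        )
    return g


def export_time_graph_graphml(tg: TimeGraph, path) -> None:
    nx.write_graphml(time_graph_to_networkx(tg), path)
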