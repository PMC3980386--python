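"""Filtering of Voronoi elements down to the static molecular paths.

Two passes remove graph elements that are not part of any molecular path:

1. *Ambient occlusion*: a vertex far outside the molecule "sees" open space
   in most directions. We cast a deterministic low-discrepancy set of rays
   from each vertex and measure the fraction that escape to the expanded
   bounding box without hitting an atom sphere; vertices receiving more light
   than a threshold are removed together with their incident edges.
2. *Probe filter*: every vertex and edge sample whose clearance to the van
   der Waals surface is below the probe radius r_p is removed, so a probe
   sphere placed anywhere on a surviving path never intersects an atom. Edge
   polylines may be truncated into several retained arcs; truncation points
   become terminal pseudo-vertices carrying clearance exactly r_p.

The connected components of the surviving graph are the path components;
each one seeds a cavity.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .config import DEFAULT_N_RAYS, DEFAULT_OCCLUSION_THRESHOLD, DEFAULT_PROBE_RADIUS
from .structures_io import Frame
from .synthetic_fixtures import _fibonacci_sphere
from .voronoi_graph import VoronoiEdge, VoronoiGraph, VoronoiVertex, _correct_onto_edge


@dataclasses.dataclass
class FilterParams:
    """Probe radius (Å), ambient-light threshold in [0, 1], and ray count."""

    probe_radius: float = DEFAULT_PROBE_RADIUS
    occlusion_threshold: float = DEFAULT_OCCLUSION_THRESHOLD
    n_rays: int = DEFAULT_N_RAYS

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if not 0.0 <= self.occlusion_threshold <= 1.0:
            raise ValueError("occlusion_threshold must be in [0, 1]")
        if self.n_rays < 32:
            raise ValueError("n_rays must be >= 32")


@dataclasses.dataclass
class PathComponent:
    """One connected component of the filtered Voronoi graph."""

    component_id: int
    vertex_ids: Set[int]
    edge_ids: Set[int]
    weight: float = 0.0  # total clearance-weighted arc length, for ordering


# ---------------------------------------------------------------------------
# Ambient occlusion
# ---------------------------------------------------------------------------

def ray_directions(n_rays: int, seed: int = 0) -> np.ndarray:
    """Deterministic low-discrepancy unit directions (rotated Fibonacci set)."""
    dirs = _fibonacci_sphere(n_rays)
    rot = Rotation.random(rng=np.random.default_rng(seed))
    return dirs @ rot.as_matrix().T


def ambient_light_fraction(
    p: np.ndarray,
    frame: Frame,
    n_rays: int = DEFAULT_N_RAYS,
    seed: int = 0,
    directions: Optional[np.ndarray] = None,
) -> float:
    """Fraction of rays from ``p`` escaping to infinity without hitting an atom.

    Raises ``ValueError`` if ``p`` lies inside an atom sphere. A precomputed
    direction set can be passed to amortise its construction over many points.
    """
    p = np.asarray(p, dtype=float)
    oc = p - frame.coords  # (n, 3)
    dist2 = np.sum(oc * oc, axis=1)
    if np.any(dist2 < frame.radii ** 2):
        raise ValueError("ambient light is undefined for a point inside an atom sphere")
    if directions is None:
        directions = ray_directions(n_rays, seed)
    # Ray-sphere: t^2 + 2 B t + C = 0 with B = d.(p - c), C = |p - c|^2 - r^2.
    B = directions @ oc.T  # (n_rays, n)
    C = dist2 - frame.radii ** 2  # (n,) > 0 since p is outside all spheres
    disc = B * B - C[None, :]
    # C > 0, so a positive root exists iff disc > 0 and -B > 0.
    blocked = np.any((disc > 0.0) & (B < 0.0), axis=1)
    return float(1.0 - np.count_nonzero(blocked) / len(directions))


# ---------------------------------------------------------------------------
# Graph filtering
# ---------------------------------------------------------------------------

def filter_graph(
    graph: VoronoiGraph,
    frame: Frame,
    params: FilterParams,
    seed: int = 0,
) -> VoronoiGraph:
    """Apply the occlusion pass and the probe pass to a Voronoi graph.

    Occlusion is evaluated at vertices only; an edge survives the occlusion
    pass iff all of its (existing) endpoint vertices survive. Unbounded
    box-clipped edges are removed whenever occlusion filtering is active
    (threshold < 1), since their free end lies outside the molecular domain.
    Vertices buried inside atoms (clearance <= 0) receive no light by
    definition. The probe pass then keeps the maximal sub-polylines whose
    samples all have clearance >= r_p, inserting pseudo-vertices of clearance
    exactly r_p at truncation points.
    """
    r_p = params.probe_radius
    dirs = ray_directions(params.n_rays, seed)

    # --- occlusion pass ------------------------------------------------
    vertex_alive = np.ones(graph.n_vertices, dtype=bool)
    for i, v in enumerate(graph.vertices):
        if v.clearance <= 0.0:
            continue  # buried point: fully occluded
        light = ambient_light_fraction(v.position, frame, directions=dirs)
        if light > params.occlusion_threshold:
            vertex_alive[i] = False

    occlusion_active = params.occlusion_threshold < 1.0
    surviving_edges: List[VoronoiEdge] = []
    for e in graph.edges:
        a, b = e.endpoints
        if occlusion_active and (a is None or b is None):
            continue
        if any(ep is not None and not vertex_alive[ep] for ep in (a, b)):
            continue
        surviving_edges.append(e)

    # --- probe pass ------------------------------------------------------
    new_vertices: List[VoronoiVertex] = []
    old_to_new: Dict[int, int] = {}
    for i, v in enumerate(graph.vertices):
        if vertex_alive[i] and v.clearance >= r_p:
            old_to_new[i] = len(new_vertices)
            new_vertices.append(v)

    new_edges: List[VoronoiEdge] = []
    for e in surviving_edges:
        P = frame.coords[list(e.generators)]
        R = frame.radii[list(e.generators)]
        for arc_samples, start_kind, end_kind in _qualifying_runs(e.samples, r_p, P, R):
            ends: List[Optional[int]] = []
            for kind, endpoint_old in ((start_kind, e.endpoints[0]), (end_kind, e.endpoints[1])):
                sample = arc_samples[0] if kind is not None and len(ends) == 0 else arc_samples[-1]
                if kind == "vertex" and endpoint_old is not None and endpoint_old in old_to_new:
                    ends.append(old_to_new[endpoint_old])
                else:
                    pv = VoronoiVertex(
                        position=sample[:3].copy(),
                        clearance=float(sample[3]),
                        generators=e.generators,
                        pseudo=True,
                    )
                    ends.append(len(new_vertices))
                    new_vertices.append(pv)
            new_edges.append(
                VoronoiEdge(
                    generators=e.generators,
                    endpoints=(ends[0], ends[1]),
                    samples=arc_samples,
                )
            )

    return VoronoiGraph(
        vertices=new_vertices,
        edges=new_edges,
        frame_index=graph.frame_index,
        box=graph.box,
    )


def _qualifying_runs(samples: np.ndarray, r_p: float, P: np.ndarray, R: np.ndarray):
    """Maximal sub-polylines with clearance >= r_p, with end classification.

    Yields ``(arc_samples, start_kind, end_kind)`` where a kind is ``"vertex"``
    if the run reaches the polyline end (the original endpoint, vertex or
    box clip) and ``"pseudo"`` if the run was truncated at a crossing point of
    clearance exactly r_p, located on the true edge curve.
    """
    ok = samples[:, 3] >= r_p
    m = len(samples)
    i = 0
    while i < m:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and ok[j + 1]:
            j += 1
        rows = [samples[i : j + 1]]
        start_kind = "vertex" if i == 0 else "pseudo"
        end_kind = "vertex" if j == m - 1 else "pseudo"
        if i > 0:
            rows.insert(0, _crossing(samples[i - 1], samples[i], r_p, P, R)[None, :])
        if j < m - 1:
            rows.append(_crossing(samples[j + 1], samples[j], r_p, P, R)[None, :])
        arc = np.vstack(rows)
        if len(arc) >= 2 or (i == 0 and j == m - 1):
            yield arc, start_kind, end_kind
        i = j + 1


def _crossing(
    below: np.ndarray, above: np.ndarray, r_p: float, P: np.ndarray, R: np.ndarray
) -> np.ndarray:
    """Sample on the edge curve where clearance crosses r_p.

    Bisects the chord parameter, projecting each trial point back onto the
    three-generator equidistance locus, so the returned point lies on the
    true curve (its clearance is set to exactly r_p).
    """
    lo_t, hi_t = 0.0, 1.0  # below at lo_t, above at hi_t

    def clearance_at(t: float):
        pos = below[:3] + t * (above[:3] - below[:3])
        proj = _correct_onto_edge(pos, P, R)
        if proj is None:
            return None, pos
        return float(np.linalg.norm(proj - P[0]) - R[0]), proj

    pos_best = None
    for _ in range(60):
        mid = 0.5 * (lo_t + hi_t)
        cl, pos = clearance_at(mid)
        if cl is None:
            break  # projection failed; fall back to linear interpolation
        if abs(cl - r_p) < 1e-12:
            pos_best = pos
            break
        if cl < r_p:
            lo_t = mid
        else:
            hi_t = mid
            pos_best = pos
        if hi_t - lo_t < 1e-12:
            break
    if pos_best is None:
        c0, c1 = below[3], above[3]
        t = 0.0 if c1 == c0 else float(np.clip((r_p - c0) / (c1 - c0), 0.0, 1.0))
        pos_best = below[:3] + t * (above[:3] - below[:3])
    return np.array([pos_best[0], pos_best[1], pos_best[2], r_p])


# ---------------------------------------------------------------------------
# Path components
# ---------------------------------------------------------------------------

def connected_components(graph: VoronoiGraph) -> List[PathComponent]:
    """Partition the filtered graph into path components.

    Components are ordered by descending total clearance-weighted arc length
    (ties broken by their sorted vertex ids) so numbering is reproducible.
    """
    parent = list(range(graph.n_vertices))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for e in graph.edges:
        a, b = e.endpoints
        if a is not None and b is not None:
            union(a, b)

    groups: Dict[int, PathComponent] = {}
    for vid in range(graph.n_vertices):
        root = find(vid)
        comp = groups.setdefault(root, PathComponent(-1, set(), set()))
        comp.vertex_ids.add(vid)
    for eid, e in enumerate(graph.edges):
        a = e.endpoints[0] if e.endpoints[0] is not None else e.endpoints[1]
        if a is None:
            continue
        comp = groups[find(a)]
        comp.edge_ids.add(eid)
        seg = np.linalg.norm(np.diff(e.samples[:, :3], axis=0), axis=1)
        mid_cl = 0.5 * (e.samples[:-1, 3] + e.samples[1:, 3])
        comp.weight += float(np.sum(seg * mid_cl))

    ordered = sorted(
        groups.values(), key=lambda c: (-c.weight, tuple(sorted(c.vertex_ids)))
    )
    for k, comp in enumerate(ordered):
        comp.component_id = k
    return ordered
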