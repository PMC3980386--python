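"""Vertex-edge graph of the additively weighted Voronoi diagram of spheres.

The diagram partitions space by the signed distance to sphere surfaces,
``d_i(p) = ||p - p_i|| - r_i``. Its vertices are centers of empty spheres
tangent to four atoms; its edges are the loci of points equidistant to three
atoms. Together they carry the complete topological skeleton of the distance
function (maxima, index-2 saddles, and connecting separatrices) — i.e. all
paths through a molecule along which the clearance to the van der Waals
surface is locally maximal. Only this graph is computed; facets and regions
are never materialised.

Vertices are found by solving the tangency (Apollonius) system for candidate
4-subsets of spheres and keeping the solutions that satisfy the empty-sphere
property inside the expanded bounding box. Candidates come from exhaustive
enumeration for small sphere counts and from the Delaunay triangulation of
the centers for large ones (exact when all radii are equal, since the
weighted diagram then reduces to the ordinary point Voronoi diagram).

Edges are traced numerically from each vertex along the 1-dimensional
equidistance locus of each of its generator triples, with predictor-corrector
marching, until another vertex is reached (bounded edge) or the expanded
bounding box is left (unbounded edge, clipped). Each edge is stored as a
clearance-annotated polyline.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .config import DEFAULT_BOUNDING_MARGIN, DEFAULT_EXACT_ENUMERATION_LIMIT
from .structures_io import Frame, Sphere

log = logging.getLogger(__name__)

#: Tolerance on tangency residuals when accepting a vertex candidate.
TANGENCY_TOL = 1e-8
#: Slack allowed when testing the empty-sphere property. Must be well below
#: the degeneracy-breaking perturbation scale (1e-6 Å), or near-ties produce
#: spurious coincident vertices.
EMPTY_TOL = 1e-9
#: Two candidates from the same generator quadruple closer than this are the
#: same vertex (coincident quadratic roots).
VERTEX_MERGE_TOL = 1e-9
#: Candidates from *different* quadruples closer than this indicate an exact
#: degeneracy (>= 5 spheres tangent to one empty sphere).
DEGENERACY_TOL = 1e-12
#: Target chord sag of edge polylines, Å.
CHORD_SAG = 0.05


class DegenerateConfigurationError(RuntimeError):
    """Raised when the sphere configuration is degenerate.

    Apply :func:`cavipath.structures_io.perturb_positions` to the frame and
    retry.
    """


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VoronoiVertex:
    """Center of an empty sphere tangent to four atom spheres."""

    position: np.ndarray
    clearance: float
    generators: Tuple[int, ...]
    pseudo: bool = False  # terminal pseudo-vertex introduced by probe truncation

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.generators = tuple(int(g) for g in self.generators)


@dataclasses.dataclass
class VoronoiEdge:
    """Equidistance locus of three atom spheres, as a sampled polyline.

    ``samples`` has shape (m, 4): columns x, y, z, clearance. ``endpoints``
    aligns with ``samples[0]`` and ``samples[-1]``; ``None`` marks a
    box-clipped (unbounded) end.
    """

    generators: Tuple[int, int, int]
    endpoints: Tuple[Optional[int], Optional[int]]
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.generators = tuple(sorted(int(g) for g in self.generators))
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 4:
            raise ValueError("samples must have shape (m, 4)")

    @property
    def length(self) -> float:
        if len(self.samples) < 2:
            return 0.0
        seg = np.diff(self.samples[:, :3], axis=0)
        return float(np.linalg.norm(seg, axis=1).sum())


@dataclasses.dataclass
class VoronoiGraph:
    vertices: List[VoronoiVertex]
    edges: List[VoronoiEdge]
    frame_index: int = 0
    box: Optional[Tuple[np.ndarray, np.ndarray]] = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def weighted_distance(p: np.ndarray, s: Sphere) -> float:
    """Signed distance from ``p`` to the sphere surface: ``||p - c|| - r``."""
    return float(np.linalg.norm(np.asarray(p, float) - s.center) - s.radius)


def _weighted_distances(p: np.ndarray, coords: np.ndarray, radii: np.ndarray) -> np.ndarray:
    return np.linalg.norm(coords - np.asarray(p, float), axis=1) - radii


@dataclasses.dataclass
class VertexReport:
    """Residuals of the two defining properties of a Voronoi vertex."""

    tangency_residuals: np.ndarray  # |d_i(v) - clearance| for the 4 generators
    empty_margin: float  # min over non-generators of d_j(v) - clearance
    tol: float

    @property
    def passed(self) -> bool:
        return bool(
            np.all(self.tangency_residuals < self.tol)
            and self.empty_margin > -self.tol
        )


def verify_vertex(v: VoronoiVertex, frame: Frame, tol: float = 1e-6) -> VertexReport:
    """Check tangency to the 4 generators and the empty-sphere property."""
    d = _weighted_distances(v.position, frame.coords, frame.radii)
    gen = list(v.generators)
    tangency = np.abs(d[gen] - v.clearance)
    mask = np.ones(frame.n_spheres, dtype=bool)
    mask[gen] = False
    empty_margin = float((d[mask] - v.clearance).min()) if mask.any() else np.inf
    return VertexReport(tangency_residuals=tangency, empty_margin=empty_margin, tol=tol)


# ---------------------------------------------------------------------------
# Vertex computation
# ---------------------------------------------------------------------------

def _drop_contained_spheres(coords: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Indices of spheres not entirely contained in another sphere."""
    n = len(coords)
    keep = np.ones(n, dtype=bool)
    tree = cKDTree(coords)
    rmax = radii.max()
    for i in range(n):
        for j in tree.query_ball_point(coords[i], rmax + radii[i]):
            if i == j or not keep[j]:
                continue
            d = np.linalg.norm(coords[i] - coords[j])
            if d + radii[i] <= radii[j]:
                keep[i] = False
                break
    if not keep.all():
        log.info("dropped %d spheres contained in larger spheres", (~keep).sum())
    return np.flatnonzero(keep)


def _solve_quadruples(
    coords: np.ndarray, radii: np.ndarray, quads: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the tangency system for each 4-subset of spheres.

    For generators (p_i, r_i), a vertex (v, c) satisfies ||v - p_i|| = c + r_i.
    Subtracting the first equation from the others yields a linear system
    v = v0 + c * v1; substitution back gives a quadratic in c. Returns
    positions (m, 3), clearances (m,) and quadruple rows (m, 4) of candidates
    that pass the tangency residual check.
    """
    if len(quads) == 0:
        return np.empty((0, 3)), np.empty(0), np.empty((0, 4), dtype=int)
    P = coords[quads]  # (m, 4, 3)
    R = radii[quads]  # (m, 4)
    p0 = P[:, 0, :]
    r0 = R[:, 0]
    A = 2.0 * (P[:, 1:, :] - p0[:, None, :])  # (m, 3, 3)
    g = 2.0 * (R[:, 1:] - r0[:, None])  # (m, 3)
    b = (
        np.sum(P[:, 1:, :] ** 2, axis=2)
        - np.sum(p0 ** 2, axis=1)[:, None]
        - (R[:, 1:] ** 2 - (r0 ** 2)[:, None])
    )  # (m, 3)

    det = np.linalg.det(A)
    ok = np.abs(det) > 1e-12
    if not ok.any():
        return np.empty((0, 3)), np.empty(0), np.empty((0, 4), dtype=int)
    A, g, b = A[ok], g[ok], b[ok]
    P, R, p0, r0 = P[ok], R[ok], p0[ok], r0[ok]
    quads = quads[ok]

    v0 = np.linalg.solve(A, b[..., None])[..., 0]  # (m, 3)
    v1 = -np.linalg.solve(A, g[..., None])[..., 0]  # (m, 3)

    w = v0 - p0
    qa = np.sum(v1 * v1, axis=1) - 1.0
    qb = 2.0 * (np.sum(v1 * w, axis=1) - r0)
    qc = np.sum(w * w, axis=1) - r0 ** 2

    pos_list, cl_list, quad_list = [], [], []
    # Quadratic roots (two branches) plus the near-linear fallback.
    disc = qb * qb - 4.0 * qa * qc
    lin = np.abs(qa) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        sq = np.sqrt(np.where(disc >= 0, disc, np.nan))
        roots = [
            np.where(lin, np.nan, (-qb + sq) / (2.0 * qa)),
            np.where(lin, np.nan, (-qb - sq) / (2.0 * qa)),
            np.where(lin & (np.abs(qb) > 1e-300), -qc / qb, np.nan),
        ]
    for c in roots:
        valid = np.isfinite(c)
        if not valid.any():
            continue
        cv = c[valid]
        vv = v0[valid] + cv[:, None] * v1[valid]
        # Tangency residual check kills the spurious sign branch.
        dist = np.linalg.norm(vv[:, None, :] - P[valid], axis=2)  # (k, 4)
        resid = np.abs(dist - (cv[:, None] + R[valid]))
        good = np.all(resid < TANGENCY_TOL, axis=1)
        if good.any():
            pos_list.append(vv[good])
            cl_list.append(cv[good])
            quad_list.append(quads[valid][good])
    if not pos_list:
        return np.empty((0, 3)), np.empty(0), np.empty((0, 4), dtype=int)
    return np.vstack(pos_list), np.concatenate(cl_list), np.vstack(quad_list)


def _candidate_quadruples(coords: np.ndarray, exact_limit: int) -> "itertools.chain | list":
    n = len(coords)
    if n <= exact_limit:
        quads = np.array(list(itertools.combinations(range(n), 4)), dtype=int)
        return [quads]
    tri = Delaunay(coords)
    quads = np.sort(tri.simplices.astype(int), axis=1)
    quads = np.unique(quads, axis=0)
    return [quads]


def compute_voronoi_graph(
    frame: Frame,
    bounding_margin: float = DEFAULT_BOUNDING_MARGIN,
    *,
    trace_edges: bool = True,
    exact_enumeration_limit: int = DEFAULT_EXACT_ENUMERATION_LIMIT,
) -> VoronoiGraph:
    """Compute the Voronoi vertex-edge graph of a frame's spheres.

    All vertices inside the frame bounding box expanded by ``bounding_margin``
    are reported; unbounded edges are clipped at that box. The frame should be
    perturbed first (see :func:`cavipath.structures_io.perturb_positions`);
    exact degeneracies raise :class:`DegenerateConfigurationError`.
    """
    if frame.n_spheres < 4:
        raise ValueError("at least 4 spheres are required for a Voronoi vertex")
    lo, hi = frame.bounding_box(margin=bounding_margin)

    keep_idx = _drop_contained_spheres(frame.coords, frame.radii)
    coords = frame.coords[keep_idx]
    radii = frame.radii[keep_idx]
    if len(coords) < 4:
        raise ValueError("fewer than 4 non-contained spheres")

    positions_parts, clearances_parts, quads_parts = [], [], []
    for quad_block in _candidate_quadruples(coords, exact_enumeration_limit):
        # Chunk very large blocks to bound memory.
        for start in range(0, len(quad_block), 500_000):
            chunk = quad_block[start : start + 500_000]
            pos, cl, qd = _solve_quadruples(coords, radii, chunk)
            if len(pos) == 0:
                continue
            inbox = np.all((pos >= lo) & (pos <= hi), axis=1)
            pos, cl, qd = pos[inbox], cl[inbox], qd[inbox]
            if len(pos) == 0:
                continue
            # Empty-sphere property against all spheres.
            ok = np.ones(len(pos), dtype=bool)
            for j0 in range(0, len(coords), 512):
                block = coords[j0 : j0 + 512]
                rblock = radii[j0 : j0 + 512]
                d = (
                    np.linalg.norm(pos[:, None, :] - block[None, :, :], axis=2)
                    - rblock[None, :]
                )
                margin = d - cl[:, None]
                # Ignore the 4 generators (their margin is ~0 by tangency).
                for col, jglob in enumerate(range(j0, j0 + len(block))):
                    margin[:, col] = np.where(
                        np.any(qd == jglob, axis=1), np.inf, margin[:, col]
                    )
                ok &= margin.min(axis=1) > -EMPTY_TOL
            positions_parts.append(pos[ok])
            clearances_parts.append(cl[ok])
            quads_parts.append(qd[ok])

    if positions_parts:
        positions = np.vstack(positions_parts)
        clearances = np.concatenate(clearances_parts)
        quads = np.vstack(quads_parts)
    else:
        positions = np.empty((0, 3))
        clearances = np.empty(0)
        quads = np.empty((0, 4), dtype=int)

    # Deduplicate (two quadratic roots can coincide; exact degeneracies give
    # coincident vertices with different generator sets).
    if len(positions) > 1:
        tree = cKDTree(positions)
        pairs = tree.query_pairs(VERTEX_MERGE_TOL, output_type="ndarray")
        drop = set()
        for i, j in pairs:
            if tuple(quads[i]) != tuple(quads[j]):
                if np.linalg.norm(positions[i] - positions[j]) < DEGENERACY_TOL:
                    raise DegenerateConfigurationError(
                        "coincident Voronoi vertices with different generators "
                        "detected; perturb the frame (perturb_positions) and retry"
                    )
                continue  # distinct near-degenerate vertices: keep both
            drop.add(int(max(i, j)))
        if drop:
            keep = np.array([i for i in range(len(positions)) if i not in drop])
            positions, clearances, quads = positions[keep], clearances[keep], quads[keep]

    # Deterministic ordering.
    order = np.lexsort((positions[:, 2], positions[:, 1], positions[:, 0]))
    positions, clearances, quads = positions[order], clearances[order], quads[order]

    vertices = [
        VoronoiVertex(
            position=positions[i],
            clearance=float(clearances[i]),
            generators=tuple(int(keep_idx[g]) for g in sorted(quads[i])),
        )
        for i in range(len(positions))
    ]

    edges: List[VoronoiEdge] = []
    if trace_edges and vertices:
        edges = _trace_all_edges(frame, vertices, (lo, hi))

    return VoronoiGraph(
        vertices=vertices, edges=edges, frame_index=frame.time_index, box=(lo, hi)
    )


# ---------------------------------------------------------------------------
# Edge tracing
# ---------------------------------------------------------------------------

def _edge_tangent(x: np.ndarray, P: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Unit tangent of the 3-sphere equidistance locus at ``x`` (unoriented)."""
    u = (x - P) / np.linalg.norm(x - P, axis=1)[:, None]
    t = np.cross(u[0] - u[1], u[0] - u[2])
    norm = np.linalg.norm(t)
    if norm < 1e-14:
        raise DegenerateConfigurationError("degenerate edge tangent")
    return t / norm


def _correct_onto_edge(
    x: np.ndarray, P: np.ndarray, R: np.ndarray, tol: float = 1e-10, max_iter: int = 8
) -> Optional[np.ndarray]:
    """Gauss-Newton projection onto the locus d_1 = d_2 = d_3."""
    x = x.copy()
    for _ in range(max_iter):
        diff = x - P
        dist = np.linalg.norm(diff, axis=1)
        if np.any(dist < 1e-12):
            return None
        d = dist - R
        g = np.array([d[0] - d[1], d[0] - d[2]])
        if np.max(np.abs(g)) < tol:
            return x
        u = diff / dist[:, None]
        J = np.array([u[0] - u[1], u[0] - u[2]])  # (2, 3)
        JJt = J @ J.T
        try:
            lam = np.linalg.solve(JJt, g)
        except np.linalg.LinAlgError:
            return None
        x = x - J.T @ lam
    d = np.linalg.norm(x - P, axis=1) - R
    resid = max(abs(d[0] - d[1]), abs(d[0] - d[2]))
    return x if resid < 1e-7 else None


def _trace_all_edges(
    frame: Frame,
    vertices: List[VoronoiVertex],
    box: Tuple[np.ndarray, np.ndarray],
) -> List[VoronoiEdge]:
    lo, hi = box
    coords = frame.coords
    radii = frame.radii
    vpos = np.array([v.position for v in vertices])
    vcl = np.array([v.clearance for v in vertices])

    triple_map: Dict[Tuple[int, int, int], List[int]] = {}
    for vid, v in enumerate(vertices):
        for T in itertools.combinations(v.generators, 3):
            triple_map.setdefault(tuple(sorted(T)), []).append(vid)

    done: set = set()
    edges: List[VoronoiEdge] = []
    for vid, v in enumerate(vertices):
        for T in itertools.combinations(v.generators, 3):
            T = tuple(sorted(T))
            if (vid, T) in done:
                continue
            g4 = next(g for g in v.generators if g not in T)
            edge = _trace_edge(
                frame, vid, T, g4, vertices, triple_map, lo, hi, coords, radii
            )
            done.add((vid, T))
            if edge is None:
                continue
            if edge.endpoints[1] is not None:
                done.add((edge.endpoints[1], T))
            edges.append(edge)
    return edges


def _trace_edge(
    frame: Frame,
    vid: int,
    T: Tuple[int, int, int],
    g4: int,
    vertices: List[VoronoiVertex],
    triple_map: Dict[Tuple[int, int, int], List[int]],
    lo: np.ndarray,
    hi: np.ndarray,
    coords: np.ndarray,
    radii: np.ndarray,
) -> Optional[VoronoiEdge]:
    v = vertices[vid]
    P = coords[list(T)]
    R = radii[list(T)]
    x0 = v.position

    try:
        tan = _edge_tangent(x0, P, R)
    except DegenerateConfigurationError:
        return None
    # Orient away from the 4th generator's region: moving along the edge, the
    # 4th sphere must recede relative to the generators.
    u4 = (x0 - coords[g4]) / np.linalg.norm(x0 - coords[g4])
    u1 = (x0 - P[0]) / np.linalg.norm(x0 - P[0])
    sense = float(np.dot(u4 - u1, tan))
    if abs(sense) < 1e-12:
        return None
    if sense < 0:
        tan = -tan

    others = [w for w in triple_map[T] if w != vid]
    other_pos = np.array([vertices[w].position for w in others]) if others else None

    # Non-generator spheres, for detecting a missed vertex crossing.
    mask = np.ones(len(coords), dtype=bool)
    mask[list(T)] = False
    nong_coords = coords[mask]
    nong_radii = radii[mask]

    h_max = 0.35
    h_min = 1e-5
    if other_pos is not None:
        dmin = float(np.linalg.norm(other_pos - x0, axis=1).min())
        h = max(min(h_max, dmin / 4.0), h_min)
    else:
        h = 0.1

    samples = [np.concatenate([x0, [v.clearance]])]
    x = x0
    prev_tan = tan
    end_vid: Optional[int] = None
    unbounded = False
    for _ in range(20000):
        stepped = False
        while True:
            xp = _correct_onto_edge(x + h * prev_tan, P, R)
            if xp is not None and np.linalg.norm(xp - x) <= 0.1 * h:
                xp = None  # corrector collapsed the step; retry smaller
            if xp is not None:
                try:
                    new_tan = _edge_tangent(xp, P, R)
                except DegenerateConfigurationError:
                    xp = None
            if xp is None:
                if h <= h_min * 1.01:
                    unbounded = False
                    end_vid = None
                    stepped = False
                    break
                h = max(h / 2.0, h_min)
                continue
            if np.dot(new_tan, prev_tan) < 0:
                new_tan = -new_tan
            cos_ang = float(np.clip(np.dot(new_tan, prev_tan), -1.0, 1.0))
            if cos_ang < np.cos(np.radians(25.0)) and h > h_min * 1.01:
                h = max(h / 2.0, h_min)
                continue
            stepped = True
            break
        if not stepped:
            break  # cannot continue; emit what we have (truncated)

        clearance = float(np.linalg.norm(xp - P[0]) - R[0])

        # Arrived at another vertex of this triple?
        if other_pos is not None:
            dists = np.linalg.norm(other_pos - xp, axis=1)
            k = int(np.argmin(dists))
            w = others[k]
            if dists[k] < max(1.5 * h, 1e-6) and abs(
                vertices[w].clearance - clearance
            ) < max(3.0 * h, 1e-6):
                end_vid = w
                samples.append(
                    np.concatenate([vertices[w].position, [vertices[w].clearance]])
                )
                break

        # Left the expanded bounding box?
        if np.any(xp < lo) or np.any(xp > hi):
            xc = _clip_to_box(x, xp, lo, hi)
            xc2 = _correct_onto_edge(xc, P, R)
            if xc2 is not None:
                xc = xc2
            cl = float(np.linalg.norm(xc - P[0]) - R[0])
            samples.append(np.concatenate([xc, [cl]]))
            unbounded = True
            break

        # Crossed into another sphere's region => missed vertex; truncate.
        if len(nong_coords):
            dmin = float(
                (np.linalg.norm(nong_coords - xp, axis=1) - nong_radii).min()
            )
            if dmin < clearance - 1e-5:
                log.debug("edge trace left Voronoi set without snapping; truncated")
                break

        samples.append(np.concatenate([xp, [clearance]]))
        x = xp
        prev_tan = new_tan
        if cos_ang > np.cos(np.radians(8.0)):
            h = min(h * 1.5, h_max)

    if len(samples) < 2:
        return None
    endpoints = (vid, end_vid if not unbounded else None)
    arr = _refine_interior_minima(np.array(samples), P, R)
    return VoronoiEdge(generators=T, endpoints=endpoints, samples=arr)


def _refine_interior_minima(samples: np.ndarray, P: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Insert samples at interior clearance minima of an edge polyline.

    The clearance minimum along a Voronoi edge is an index-2 saddle of the
    distance function — the constriction that decides whether a probe can
    pass — so it must appear in the polyline even when it falls between
    marching steps. A minimum inside a segment is detected by a sign change
    of the clearance derivative along the curve and located by golden-section
    search with projection onto the edge locus.
    """

    def slope(x: np.ndarray, direction: np.ndarray) -> float:
        # d(clearance)/ds along the curve, oriented by ``direction``.
        try:
            t = _edge_tangent(x, P, R)
        except DegenerateConfigurationError:
            return 0.0
        if np.dot(t, direction) < 0:
            t = -t
        u1 = (x - P[0]) / np.linalg.norm(x - P[0])
        return float(np.dot(u1, t))

    def clearance_of(x: np.ndarray) -> float:
        return float(np.linalg.norm(x - P[0]) - R[0])

    out = [samples[0]]
    for k in range(len(samples) - 1):
        x1, x2 = samples[k, :3], samples[k + 1, :3]
        d = x2 - x1
        if slope(x1, d) < 0.0 < slope(x2, d):
            lo_t, hi_t = 0.0, 1.0
            best = None
            gr = (np.sqrt(5.0) - 1.0) / 2.0
            c_t = lo_t + (1 - gr) * (hi_t - lo_t)
            d_t = lo_t + gr * (hi_t - lo_t)

            def eval_at(t):
                proj = _correct_onto_edge(x1 + t * d, P, R)
                return None if proj is None else (clearance_of(proj), proj)

            fc, fd = eval_at(c_t), eval_at(d_t)
            for _ in range(40):
                if fc is None or fd is None:
                    break
                if fc[0] < fd[0]:
                    hi_t, d_t, fd = d_t, c_t, fc
                    c_t = lo_t + (1 - gr) * (hi_t - lo_t)
                    fc = eval_at(c_t)
                else:
                    lo_t, c_t, fc = c_t, d_t, fd
                    d_t = lo_t + gr * (hi_t - lo_t)
                    fd = eval_at(d_t)
            for f in (fc, fd):
                if f is not None and (best is None or f[0] < best[0]):
                    best = f
            if best is not None and best[0] < min(samples[k, 3], samples[k + 1, 3]) - 1e-12:
                out.append(np.concatenate([best[1], [best[0]]]))
        out.append(samples[k + 1])
    return np.array(out)


def _clip_to_box(x_in: np.ndarray, x_out: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Point where segment x_in -> x_out crosses the box boundary."""
    t = 1.0
    d = x_out - x_in
    for k in range(3):
        if abs(d[k]) < 1e-300:
            continue
        if x_out[k] < lo[k]:
            t = min(t, (lo[k] - x_in[k]) / d[k])
        if x_out[k] > hi[k]:
            t = min(t, (hi[k] - x_in[k]) / d[k])
    return x_in + max(t, 0.0) * d


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def graph_to_json_dict(graph: VoronoiGraph) -> dict:
    return {
        "frame_index": graph.frame_index,
        "vertices": [
            {
                "position": [float(x) for x in v.position],
                "clearance": float(v.clearance),
                "generators": list(v.generators),
                "pseudo": bool(v.pseudo),
            }
            for v in graph.vertices
        ],
        "edges": [
            {
                "generators": list(e.generators),
                "endpoints": [None if i is None else int(i) for i in e.endpoints],
                "samples": [[float(x) for x in row] for row in e.samples],
            }
            for e in graph.edges
        ],
    }


def export_graph_json(graph: VoronoiGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(graph_to_json_dict(graph), fh)


def graph_to_networkx(graph: VoronoiGraph) -> nx.Graph:
    """Vertex-edge connectivity as a networkx graph (no sample polylines)."""
    g = nx.Graph()
    for i, v in enumerate(graph.vertices):
        g.add_node(
            i,
            x=float(v.position[0]),
            y=float(v.position[1]),
            z=float(v.position[2]),
            clearance=float(v.clearance),
            generators=",".join(map(str, v.generators)),
            pseudo=bool(v.pseudo),
        )
    for k, e in enumerate(graph.edges):
        a, b = e.endpoints
        if a is not None and b is not None:
            g.add_edge(a, b, edge_id=k, generators=",".join(map(str, e.generators)))
    return g


def export_graphml(graph: VoronoiGraph, path) -> None:
    nx.write_graphml(graph_to_networkx(graph), path)
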