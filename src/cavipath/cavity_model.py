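"""Cavities as unions of empty spheres placed on the filtered Voronoi graph.

Each path component's cavity is approximated by the empty tangent spheres at
its Voronoi vertices plus spheres along its edges, sampled densely enough
that the largest circle inside the intersection of any two consecutive
spheres has radius at least r_p. This guarantees a probe sphere can roll
along the whole path without leaving the sphere union or touching an atom.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .path_filtering import PathComponent
from .structures_io import Frame, Sphere
from .volumetrics import largest_intersection_circle_radius
from .voronoi_graph import VoronoiGraph

#: Numerical slack on the r_p comparisons (placement criterion and radii).
CRITERION_TOL = 1e-9


class EdgeSamplingError(RuntimeError):
    """The placement criterion cannot be met between adjacent geometric
    samples even at maximal refinement (the polyline sampling is too coarse)."""


@dataclasses.dataclass
class Cavity:
    """One path component's union of empty spheres in one frame."""

    frame_index: int
    cavity_id: int
    centers: np.ndarray  # (m, 3), Å
    radii: np.ndarray  # (m,), Å
    component_ref: int = 0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if len(self.centers) != len(self.radii):
            raise ValueError("centers and radii must have equal length")

    @property
    def n_spheres(self) -> int:
        return len(self.radii)

    @property
    def spheres(self) -> List[Sphere]:
        return [Sphere(self.centers[i].copy(), float(self.radii[i])) for i in range(self.n_spheres)]

    @property
    def aabb(self) -> Tuple[np.ndarray, np.ndarray]:
        """Axis-aligned box of the sphere extents (center ± radius)."""
        if self.n_spheres == 0:
            return np.zeros(3), np.zeros(3)
        lo = (self.centers - self.radii[:, None]).min(axis=0)
        hi = (self.centers + self.radii[:, None]).max(axis=0)
        return lo, hi


def empty_radius_function(frame: Frame, k: int = 32) -> Callable[[np.ndarray], float]:
    """Largest empty-sphere radius centered at a point (min weighted distance).

    Uses the k nearest atom centers; exact for uniform radii and a tight
    approximation otherwise (k bounded by the atom count).
    """
    tree = cKDTree(frame.coords)
    k = min(k, frame.n_spheres)

    def fn(p: np.ndarray) -> float:
        d, idx = tree.query(np.asarray(p, float), k=k)
        return float(np.min(np.atleast_1d(d) - frame.radii[np.atleast_1d(idx)]))

    return fn


def sample_edge_spheres(
    edge_arc: np.ndarray,
    r_p: float,
    radius_fn: Optional[Callable[[np.ndarray], float]] = None,
    projector: Optional[Callable[[np.ndarray], Optional[np.ndarray]]] = None,
    max_levels: int = 24,
) -> List[Sphere]:
    """Spheres along one edge arc satisfying the probe-continuity criterion.

    ``edge_arc`` is an (m, 4) polyline of (x, y, z, clearance) samples, all
    with clearance >= r_p. Between each consecutive pair the largest inscribed
    intersection-circle radius must reach r_p; midpoints are inserted until it
    does, up to ``max_levels`` of refinement. Inserted midpoints are projected
    back onto the true edge curve by ``projector`` when given (keeping the
    empty-sphere property exact near clearance minima), and their radius is
    recomputed by ``radius_fn`` when given, else interpolated.
    """
    arc = np.asarray(edge_arc, dtype=float)
    if arc.ndim != 2 or arc.shape[1] != 4:
        raise ValueError("edge_arc must have shape (m, 4)")
    if np.any(arc[:, 3] < r_p - CRITERION_TOL):
        raise ValueError("all arc clearances must be >= r_p")
    if len(arc) == 1:
        return [Sphere(arc[0, :3].copy(), float(arc[0, 3]))]

    out: List[Sphere] = [Sphere(arc[0, :3].copy(), float(arc[0, 3]))]
    for k in range(len(arc) - 1):
        _refine_pair(arc[k], arc[k + 1], 0, r_p, radius_fn, projector, max_levels, out)
    return out


def _refine_pair(s1, s2, level, r_p, radius_fn, projector, max_levels, out: List[Sphere]) -> None:
    a = Sphere(s1[:3].copy(), float(s1[3]))
    b = Sphere(s2[:3].copy(), float(s2[3]))
    circ = largest_intersection_circle_radius(a, b)
    if circ is not None and circ >= r_p - CRITERION_TOL:
        out.append(b)
        return
    if level >= max_levels or np.linalg.norm(s2[:3] - s1[:3]) < 1e-12:
        raise EdgeSamplingError(
            "probe-continuity criterion unattainable between adjacent edge "
            f"samples after {max_levels} refinement levels; the edge polyline "
            "sampling is too coarse"
        )
    mid = _refined_point(s1, s2, r_p, radius_fn, projector)
    if mid is None:
        raise EdgeSamplingError(
            "no refined edge point with clearance >= r_p found between "
            "adjacent samples; the edge polyline sampling is too coarse"
        )
    _refine_pair(s1, mid, level + 1, r_p, radius_fn, projector, max_levels, out)
    _refine_pair(mid, s2, level + 1, r_p, radius_fn, projector, max_levels, out)


def _refined_point(s1, s2, r_p, radius_fn, projector) -> Optional[np.ndarray]:
    """A point between two samples with empty radius >= r_p, near the middle.

    Tries the chord midpoint first (projected onto the edge curve when a
    projector is given), then nearby chord parameters; a projection that
    overshoots past either parent sample (which can happen where the curve
    bends sharply near a vertex) is rejected.
    """
    seg = s2[:3] - s1[:3]
    seg2 = float(seg @ seg)
    for t in (0.5, 0.375, 0.625, 0.25, 0.75):
        for use_proj in ((True, False) if projector is not None else (False,)):
            pos = s1[:3] + t * seg
            if use_proj:
                proj = projector(pos)
                if proj is None:
                    continue
                pos = proj
                s = float((pos - s1[:3]) @ seg)
                if not 0.0 < s < seg2:
                    continue  # overshot past a parent sample
            if radius_fn is not None:
                r = float(radius_fn(pos))
            else:
                r = float(s1[3] + t * (s2[3] - s1[3]))
            if r >= r_p - CRITERION_TOL:
                return np.array([pos[0], pos[1], pos[2], r])
    return None


def build_cavities(
    components: Sequence[PathComponent],
    graph: VoronoiGraph,
    r_p: float,
    frame: Optional[Frame] = None,
) -> List[Cavity]:
    """One cavity per path component: vertex spheres plus edge-sampled spheres.

    When ``frame`` is given, refined edge spheres recompute their radius from
    the actual atom distances (keeping the empty-sphere property exact);
    otherwise clearances are interpolated along the polyline.
    """
    radius_fn = empty_radius_function(frame) if frame is not None else None

    def make_projector(e):
        if frame is None:
            return None
        from .voronoi_graph import _correct_onto_edge

        P = frame.coords[list(e.generators)]
        R = frame.radii[list(e.generators)]
        return lambda pos: _correct_onto_edge(pos, P, R)

    cavities: List[Cavity] = []
    for cid, comp in enumerate(components):
        centers: List[np.ndarray] = []
        radii: List[float] = []
        seen = set()

        def add(pos: np.ndarray, r: float) -> None:
            key = (round(float(pos[0]), 9), round(float(pos[1]), 9), round(float(pos[2]), 9))
            if key in seen:
                return
            seen.add(key)
            centers.append(np.asarray(pos, float))
            radii.append(float(r))

        for vid in sorted(comp.vertex_ids):
            v = graph.vertices[vid]
            add(v.position, v.clearance)
        for eid in sorted(comp.edge_ids):
            e = graph.edges[eid]
            for s in sample_edge_spheres(
                e.samples, r_p, radius_fn=radius_fn, projector=make_projector(e)
            ):
                add(s.center, s.radius)
        cavities.append(
            Cavity(
                frame_index=graph.frame_index,
                cavity_id=cid,
                centers=np.array(centers) if centers else np.empty((0, 3)),
                radii=np.array(radii),
                component_ref=comp.component_id,
            )
        )
    return cavities


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def cavity_to_json_dict(cavity: Cavity) -> dict:
    return {
        "frame_index": int(cavity.frame_index),
        "cavity_id": int(cavity.cavity_id),
        "component_ref": int(cavity.component_ref),
        "spheres": [
            [float(x), float(y), float(z), float(r)]
            for (x, y, z), r in zip(cavity.centers, cavity.radii)
        ],
    }


def cavity_from_json_dict(d: dict) -> Cavity:
    spheres = np.asarray(d["spheres"], dtype=float).reshape(-1, 4)
    return Cavity(
        frame_index=int(d["frame_index"]),
        cavity_id=int(d["cavity_id"]),
        centers=spheres[:, :3],
        radii=spheres[:, 3],
        component_ref=int(d.get("component_ref", 0)),
    )


def export_cavities_json(cavities: Sequence[Cavity], path, frame_index: Optional[int] = None) -> None:
    fi = frame_index if frame_index is not None else (cavities[0].frame_index if cavities else 0)
    doc = {"frame_index": int(fi), "cavities": [cavity_to_json_dict(c) for c in cavities]}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_cavities_json(path) -> Tuple[int, List[Cavity]]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return int(doc["frame_index"]), [cavity_from_json_dict(d) for d in doc["cavities"]]


def export_cavities_pdb(cavities: Sequence[Cavity], path) -> None:
    """HETATM sphere dump with the radius in the B-factor column."""
    lines = []
    serial = 1
    for cav in cavities:
        for (x, y, z), r in zip(cav.centers, cav.radii):
            lines.append(
                f"HETATM{serial % 100000:5d}  SPH CAV {chr(65 + cav.cavity_id % 26)}"
                f"{(cav.cavity_id + 1) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{r:6.2f}          "
                f" C  \n"
            )
            serial += 1
    with open(path, "w", encoding="utf-8") as fh:
        fh.writelines(lines)
        fh.write("END\n")
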