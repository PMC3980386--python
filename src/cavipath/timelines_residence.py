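"""Timeline tables (split/merge, evolution) and residence-probability grids.

These are the numeric structures behind compact single-image summaries of
cavity dynamics: a split/merge layout (one polyline per identity, thickness
encoding volume, with explicit event rows), per-identity evolution profiles
(projection interval of the cavity along a chosen axis per frame), and
residence-probability grids (for each cube of a regular sampling, the
proportion of frames in which its center lies inside the selected cavities).
Rendering is left to external viewers; grids export as OpenDX scalar fields.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cavity_model import Cavity
from .cavity_tracing import TimeGraph
from .config import DEFAULT_CUBE_LENGTH
from .volumetrics import VolumeGrid, _grid_dims, occupancy_grid


# ---------------------------------------------------------------------------
# Split / merge timeline
# ---------------------------------------------------------------------------

def split_merge_timeline(
    tg: TimeGraph, t_range: Optional[Tuple[int, int]] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Layout table and event list of the split-and-merge timeline.

    Returns ``(rows, events)``: one row per (frame, identity) with a simple
    top-to-bottom row index and the cavity volume (the drawn line thickness),
    plus one event row per split/merge with parent and child identities.
    Events are recorded at the later frame of the transition.
    """
    if t_range is None:
        frames = tg.frames
    else:
        frames = [t for t in tg.frames if t_range[0] <= t <= t_range[1]]
    fset = set(frames)

    identities = sorted(
        {
            tg.nodes[k]["identity"]
            for k in tg.nodes
            if k[0] in fset and tg.nodes[k]["identity"] is not None
        }
    )
    row_of = {ident: i for i, ident in enumerate(identities)}

    rows = []
    for (f, c), v in sorted(tg.nodes.items()):
        if f not in fset or v["identity"] is None:
            continue
        rows.append(
            {
                "frame": f,
                "identity": v["identity"],
                "row": row_of[v["identity"]],
                "volume": v["volume"],
            }
        )
    rows_df = pd.DataFrame(rows, columns=["frame", "identity", "row", "volume"])

    events = []
    fwd: Dict[Tuple[int, int], list] = {}
    bwd: Dict[Tuple[int, int], list] = {}
    for e in tg.edges:
        if e.frame_t in fset and e.frame_t + 1 in fset:
            fwd.setdefault(e.node_t, []).append(e.node_t1)
            bwd.setdefault(e.node_t1, []).append(e.node_t)
    for key, children in sorted(fwd.items()):
        if len(children) >= 2:
            events.append(
                {
                    "frame": key[0] + 1,
                    "event": "split",
                    "parents": _ids(tg, [key]),
                    "children": _ids(tg, children),
                }
            )
    for key, parents in sorted(bwd.items()):
        if len(parents) >= 2:
            events.append(
                {
                    "frame": key[0],
                    "event": "merge",
                    "parents": _ids(tg, parents),
                    "children": _ids(tg, [key]),
                }
            )
    events_df = pd.DataFrame(
        sorted(events, key=lambda r: (r["frame"], r["event"])),
        columns=["frame", "event", "parents", "children"],
    )
    return rows_df, events_df


def _ids(tg: TimeGraph, keys) -> str:
    vals = sorted({tg.nodes[k]["identity"] for k in keys if tg.nodes[k]["identity"] is not None})
    return "+".join(str(v) for v in vals)


# ---------------------------------------------------------------------------
# Evolution profiles
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EvolutionProfile:
    """Per-frame extent of one identity along a projection axis."""

    identity: int
    frames: List[int]
    present: List[bool]
    min_projection: List[float]  # NaN where absent
    max_projection: List[float]


def evolution_profile(
    tg: TimeGraph,
    cavities_per_frame: Sequence[Sequence[Cavity]],
    axis: Sequence[float],
) -> List[EvolutionProfile]:
    """Projection interval of each identity's cavity along ``axis``, per frame.

    The interval is [min over spheres of (center·axis − r), max of
    (center·axis + r)]; the axis must be a unit vector.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("axis must be a non-zero vector")
    if abs(norm - 1.0) > 1e-9:
        raise ValueError("axis must be a unit vector")

    by_key: Dict[Tuple[int, int], Cavity] = {}
    for cavs in cavities_per_frame:
        for cav in cavs:
            by_key[(cav.frame_index, cav.cavity_id)] = cav

    identities = sorted(
        {v["identity"] for v in tg.nodes.values() if v["identity"] is not None}
    )
    profiles = []
    for ident in identities:
        present, mins, maxs = [], [], []
        for f in tg.frames:
            key = next(
                (k for k in tg.nodes_at(f) if tg.nodes[k]["identity"] == ident), None
            )
            cav = by_key.get(key) if key is not None else None
            if cav is None or cav.n_spheres == 0:
                present.append(False)
                mins.append(float("nan"))
                maxs.append(float("nan"))
            else:
                proj = cav.centers @ axis
                present.append(True)
                mins.append(float((proj - cav.radii).min()))
                maxs.append(float((proj + cav.radii).max()))
        profiles.append(
            EvolutionProfile(
                identity=ident,
                frames=list(tg.frames),
                present=present,
                min_projection=mins,
                max_projection=maxs,
            )
        )
    return profiles


def evolution_profiles_to_dataframe(profiles: Sequence[EvolutionProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for f, pres, lo, hi in zip(p.frames, p.present, p.min_projection, p.max_projection):
            rows.append(
                {
                    "identity": p.identity,
                    "frame": f,
                    "present": int(pres),
                    "min_proj": lo,
                    "max_proj": hi,
                }
            )
    return pd.DataFrame(rows, columns=["identity", "frame", "present", "min_proj", "max_proj"])


# ---------------------------------------------------------------------------
# Residence probability
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ResidenceGrid:
    """Cube grid of occupancy proportions over a frame range."""

    grid: VolumeGrid  # occupancy holds float values in [0, 1]
    frame_range: Tuple[int, int]
    n_frames: int


def residence_probability(
    cavity_sets_per_frame: Sequence[Sequence[Cavity]],
    a: float = DEFAULT_CUBE_LENGTH,
    frame_range: Optional[Tuple[int, int]] = None,
) -> ResidenceGrid:
    """Proportion of frames in which each cube center lies inside a cavity.

    ``cavity_sets_per_frame`` holds, per frame, the spheres contributing at
    that frame (a single traced cavity or all cavities). The grid spans the
    union bounding box over all frames, anchored at its min corner with cube
    centers at origin + (i + 1/2)·a — the same convention as the volume
    grids, so a single-frame residence grid equals the occupancy grid.
    """
    if len(cavity_sets_per_frame) == 0:
        raise ValueError("at least one frame is required")
    if not a > 0:
        raise ValueError("cube length a must be > 0")
    los, his = [], []
    for cavs in cavity_sets_per_frame:
        for cav in cavs:
            if cav.n_spheres:
                lo, hi = cav.aabb
                los.append(lo)
                his.append(hi)
    if not los:
        raise ValueError("no spheres in any frame")
    lo = np.min(np.array(los), axis=0)
    hi = np.max(np.array(his), axis=0)
    dims = _grid_dims(lo, hi, a)
    T = len(cavity_sets_per_frame)
    counts = np.zeros(dims, dtype=np.int32)
    for cavs in cavity_sets_per_frame:
        if not cavs:
            continue
        centers = np.vstack([c.centers for c in cavs if c.n_spheres] or [np.empty((0, 3))])
        radii = np.concatenate([c.radii for c in cavs if c.n_spheres] or [np.empty(0)])
        counts += occupancy_grid(centers, radii, lo, dims, a).astype(np.int32)
    values = counts.astype(float) / T
    if frame_range is None:
        fs = [c.frame_index for cavs in cavity_sets_per_frame for c in cavs]
        frame_range = (min(fs), max(fs)) if fs else (0, T - 1)
    return ResidenceGrid(
        grid=VolumeGrid(origin=lo, spacing=a, dims=dims, occupancy=values),
        frame_range=frame_range,
        n_frames=T,
    )


def stable_core_count(res: ResidenceGrid, threshold: float) -> int:
    """Number of cubes with residence probability strictly above ``threshold``."""
    return int(np.count_nonzero(res.grid.occupancy > threshold))


# ---------------------------------------------------------------------------
# OpenDX export
# ---------------------------------------------------------------------------

def export_dx(grid: VolumeGrid, path, comment: str = "cavipath scalar grid") -> None:
    """Write a grid as an OpenDX scalar field readable by PyMOL/VMD/Chimera.

    Grid positions are the cube centers.
    """
    nx_, ny, nz = grid.dims
    ox, oy, oz = grid.origin + 0.5 * grid.spacing
    a = grid.spacing
    data = np.asarray(grid.occupancy, dtype=float).reshape(-1)  # x fastest-varying last
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {nx_} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {a:.6f} 0 0\n")
        fh.write(f"delta 0 {a:.6f} 0\n")
        fh.write(f"delta 0 0 {a:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx_} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {data.size} data follows\n"
        )
        for i in range(0, data.size, 3):
            fh.write(" ".join(f"{v:.6g}" for v in data[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
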