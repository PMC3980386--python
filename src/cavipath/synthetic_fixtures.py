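"""Deterministic toy molecules and scripted trajectories with known ground truth.

Every fixture is built from closed-form geometry, so the expected cavities,
clearances, component counts and split/merge events are computed from the
construction parameters — never from the algorithms under test. Fixtures use
a single atom radius so closed forms stay available.

* ``tetra_cage`` — four equal spheres at regular-tetrahedron vertices; one
  interior Voronoi vertex at the centroid with clearance
  ``edge_length * sqrt(3/8) - atom_radius``.
* ``shell_pocket`` — atoms on a spherical shell with an optional circular
  mouth; a closed shell (mouth 0°) is the ``closed_cage`` used by the
  ambient-occlusion tests.
* ``channel_tube`` — an atom-lined straight tube spanning the box, with a
  central bottleneck ring of chosen free radius; optionally drifting
  laterally over frames.
* ``splitting_dumbbell`` — two bulbs joined by a neck whose free radius
  follows a per-frame schedule; when the neck falls below the probe radius
  the single cavity splits in two (or merges, for a rising schedule).
"""

from __future__ import annotations

import dataclasses
import json
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .structures_io import AtomLabel, Frame, Trajectory, load_default_radius_table

#: Default atom radius for surface-built fixtures, Å. Matches the packaged
#: sulfur van der Waals radius so fixtures survive a PDB round trip exactly.
FIXTURE_ATOM_RADIUS = 1.8


@dataclasses.dataclass
class FixtureSpec:
    """Recipe plus ground truth for one generated fixture."""

    kind: str
    params: dict
    n_frames: int
    seed: int
    event_script: List[Tuple[int, str]] = dataclasses.field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "params": self.params,
                "n_frames": self.n_frames,
                "seed": self.seed,
                "event_script": [[int(f), str(e)] for f, e in self.event_script],
                "uniform_radius": self.params.get("atom_radius"),
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# Elementary builders
# ---------------------------------------------------------------------------

def make_tetra_cage(edge_length: float = 2.0, atom_radius: float = 1.0) -> Frame:
    """Four equal spheres at the vertices of a regular tetrahedron.

    The interior Voronoi vertex sits at the centroid with clearance
    ``edge_length * sqrt(3/8) - atom_radius`` (circumradius minus radius).
    """
    if edge_length <= 0 or atom_radius <= 0:
        raise ValueError("edge_length and atom_radius must be > 0")
    base = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    coords = base * (edge_length / np.sqrt(8.0))  # pairwise distance = edge_length
    return Frame(coords=coords, radii=np.full(4, float(atom_radius)))


def tetra_cage_clearance(edge_length: float, atom_radius: float) -> float:
    """Closed-form clearance of the tetra-cage interior vertex."""
    return edge_length * np.sqrt(3.0 / 8.0) - atom_radius


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (deterministic spherical Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_shell_pocket(
    shell_radius: float = 6.0,
    atom_radius: float = FIXTURE_ATOM_RADIUS,
    atom_count: int = 80,
    mouth_angle: float = 0.0,
) -> Frame:
    """Atoms on a spherical shell with a circular mouth of given half-angle.

    ``mouth_angle = 0`` gives a leak-free closed cage with an interior cavity
    of approximate volume ``(4/3) pi (shell_radius - atom_radius)^3``. The
    mouth opens toward +z. Raises if the shell spacing is too coarse to be
    leak-free (nearest-neighbor distance must stay below ``2 * atom_radius``).
    """
    dirs = _fibonacci_sphere(atom_count)
    coords = dirs * shell_radius
    tree = cKDTree(coords)
    dists, _ = tree.query(coords, k=2)
    if dists[:, 1].max() >= 2.0 * atom_radius:
        raise ValueError(
            "shell spacing too coarse for a leak-free cage: "
            f"max nearest-neighbor distance {dists[:, 1].max():.2f} Å "
            f">= {2 * atom_radius:.2f} Å; increase atom_count"
        )
    if mouth_angle > 0:
        polar = np.degrees(np.arccos(np.clip(dirs[:, 2], -1.0, 1.0)))
        coords = coords[polar > mouth_angle]
    return Frame(coords=coords, radii=np.full(len(coords), float(atom_radius)))


def make_closed_cage(
    shell_radius: float = 6.0,
    atom_radius: float = FIXTURE_ATOM_RADIUS,
    atom_count: int = 80,
) -> Frame:
    """Leak-free closed shell (a shell pocket with no mouth)."""
    return make_shell_pocket(shell_radius, atom_radius, atom_count, mouth_angle=0.0)


def combine_frames(*frames: Frame, time_index: int = 0) -> Frame:
    """Union of several frames' spheres as one frame."""
    return Frame(
        coords=np.vstack([f.coords for f in frames]),
        radii=np.concatenate([f.radii for f in frames]),
        time_index=time_index,
    )


def translate_frame(frame: Frame, offset: Sequence[float], time_index: Optional[int] = None) -> Frame:
    return Frame(
        coords=frame.coords + np.asarray(offset, float),
        radii=frame.radii.copy(),
        time_index=frame.time_index if time_index is None else time_index,
    )


# ---------------------------------------------------------------------------
# Surface-of-revolution builders (rings of atoms around the z axis)
# ---------------------------------------------------------------------------

def _ring(z: float, free_radius: float, atom_radius: float, spacing: float, stagger: float) -> np.ndarray:
    """One ring of atoms around the z axis leaving ``free_radius`` of clearance."""
    ring_r = free_radius + atom_radius
    m = max(int(np.ceil(2.0 * np.pi * ring_r / spacing)), 3)
    ang = 2.0 * np.pi * (np.arange(m) + stagger) / m
    return np.column_stack(
        [ring_r * np.cos(ang), ring_r * np.sin(ang), np.full(m, z)]
    )


def make_channel_tube(
    length: float = 12.0,
    bottleneck_radius: float = 2.0,
    n_frames: int = 3,
    drift: float = 0.0,
    tube_radius: float = 2.6,
    atom_radius: float = FIXTURE_ATOM_RADIUS,
    ring_spacing: float = 1.8,
) -> Trajectory:
    """Open atom-lined tube along z with a central bottleneck ring.

    The tube spans ``[-length/2, +length/2]``; every frame the whole tube is
    translated by ``drift`` Å along x. The free radius is ``tube_radius``
    everywhere except the central ring, where it is ``bottleneck_radius``.
    """
    zs = np.arange(-length / 2.0, length / 2.0 + 1e-9, ring_spacing)
    zs = zs - (zs[0] + zs[-1]) / 2.0  # center so one ring sits at z ~ 0
    rings = []
    for k, z in enumerate(zs):
        free = bottleneck_radius if abs(z) < ring_spacing / 2.0 else tube_radius
        rings.append(_ring(z, free, atom_radius, 2.2, 0.5 * (k % 2)))
    coords0 = np.vstack(rings)
    frames = [
        Frame(
            coords=coords0 + np.array([drift * t, 0.0, 0.0]),
            radii=np.full(len(coords0), float(atom_radius)),
            time_index=t,
        )
        for t in range(n_frames)
    ]
    return Trajectory(frames=frames)


def _dumbbell_profile(
    z: float, neck_free_radius: float, bulb_free_radius: float, bulb_center_z: float
) -> float:
    """Free radius of the dumbbell surface of revolution at height z.

    Two spherical bulbs joined by a cylindrical neck: the neck is a constant
    free radius, so the clearance along the connecting path has exactly one
    constriction (at the waist) and no secondary pockets.
    """
    zb, B, w = bulb_center_z, bulb_free_radius, neck_free_radius
    bulb = 0.0
    for zc in (-zb, zb):
        if abs(z - zc) < B:
            bulb = max(bulb, float(np.sqrt(B * B - (z - zc) ** 2)))
    neck = w if abs(z) <= zb else 0.0
    return max(bulb, neck, 0.0)


def _dumbbell_frame(
    neck_free_radius: float,
    ref_neck_free_radius: float,
    bulb_free_radius: float,
    bulb_center_z: float,
    atom_radius: float,
    ring_spacing: float,
    time_index: int,
) -> Frame:
    """Closed dumbbell surface: two bulbs joined by a conical neck.

    Ring atom counts are derived from the reference (widest) neck radius so
    every frame of a schedule has the identical atom list; only positions
    move as the neck tightens.
    """
    zb, B = bulb_center_z, bulb_free_radius
    z_end = zb + B
    zs = np.arange(-z_end, z_end + 1e-9, ring_spacing)
    zs = zs - (zs[0] + zs[-1]) / 2.0
    rings = []
    for k, z in enumerate(zs):
        free = _dumbbell_profile(z, neck_free_radius, B, zb)
        free_ref = _dumbbell_profile(z, ref_neck_free_radius, B, zb)
        ring_r_ref = free_ref + atom_radius
        m = max(int(np.ceil(2.0 * np.pi * ring_r_ref / 2.2)), 3)
        ring_r = free + atom_radius
        ang = 2.0 * np.pi * (np.arange(m) + 0.5 * (k % 2)) / m
        rings.append(
            np.column_stack(
                [ring_r * np.cos(ang), ring_r * np.sin(ang), np.full(m, z)]
            )
        )
    # Axial cap atoms seal the poles.
    rings.append(np.array([[0.0, 0.0, zs[0] - 0.6 * atom_radius]]))
    rings.append(np.array([[0.0, 0.0, zs[-1] + 0.6 * atom_radius]]))
    coords = np.vstack(rings)
    return Frame(
        coords=coords,
        radii=np.full(len(coords), float(atom_radius)),
        time_index=time_index,
    )


def make_splitting_dumbbell(
    n_frames: int = 10,
    neck_radius_schedule: Optional[Sequence[float]] = None,
    probe_radius: float = 1.4,
    bulb_free_radius: float = 2.6,
    bulb_center_z: float = 4.5,
    atom_radius: float = FIXTURE_ATOM_RADIUS,
    ring_spacing: float = 1.5,
) -> Tuple[Trajectory, List[Tuple[int, str]]]:
    """Two bulbs joined by a neck whose free radius follows a schedule.

    The schedule must cross ``probe_radius`` exactly once. Frames where the
    neck admits the probe hold one cavity; the others hold two. The returned
    event script records the crossing frame as a ``split`` (falling schedule)
    or ``merge`` (rising schedule).
    """
    if neck_radius_schedule is None:
        half = n_frames // 2
        neck_radius_schedule = np.concatenate(
            [np.linspace(2.0, 1.7, half), np.linspace(1.1, 0.7, n_frames - half)]
        )
    schedule = np.asarray(neck_radius_schedule, dtype=float)
    if len(schedule) != n_frames:
        raise ValueError("schedule length must equal n_frames")
    open_ = schedule >= probe_radius
    crossings = np.flatnonzero(open_[:-1] != open_[1:])
    if len(crossings) != 1:
        raise ValueError("schedule must cross probe_radius exactly once")
    event_frame = int(crossings[0] + 1)
    event = "split" if open_[0] else "merge"
    ref = float(schedule.max())
    frames = [
        _dumbbell_frame(
            float(schedule[t]),
            ref,
            bulb_free_radius,
            bulb_center_z,
            atom_radius,
            ring_spacing,
            t,
        )
        for t in range(n_frames)
    ]
    return Trajectory(frames=frames), [(event_frame, event)]


# ---------------------------------------------------------------------------
# Fixture emission (multi-model PDB + JSON sidecar)
# ---------------------------------------------------------------------------

_KINDS = ("tetra_cage", "shell_pocket", "closed_cage", "channel_tube", "splitting_dumbbell")


def build_fixture(kind: str, n_frames: int = 1, seed: int = 0, **params) -> Tuple[Trajectory, FixtureSpec]:
    """Build a fixture trajectory plus its spec/ground-truth record."""
    events: List[Tuple[int, str]] = []
    if kind == "tetra_cage":
        frame = make_tetra_cage(**params)
        traj = Trajectory(frames=[dataclasses.replace(frame, time_index=t) for t in range(n_frames)])
    elif kind in ("shell_pocket", "closed_cage"):
        fn = make_shell_pocket if kind == "shell_pocket" else make_closed_cage
        frame = fn(**params)
        traj = Trajectory(frames=[dataclasses.replace(frame, time_index=t) for t in range(n_frames)])
    elif kind == "channel_tube":
        traj = make_channel_tube(n_frames=n_frames, **params)
    elif kind == "splitting_dumbbell":
        traj, events = make_splitting_dumbbell(n_frames=n_frames, **params)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {_KINDS}")
    params = dict(params)
    params.setdefault(
        "atom_radius",
        float(traj.frames[0].radii[0]) if len(set(traj.frames[0].radii)) == 1 else None,
    )
    spec = FixtureSpec(kind=kind, params=params, n_frames=traj.n_frames, seed=seed, event_script=events)
    return traj, spec


def _element_for_radius(radius: float) -> str:
    table = load_default_radius_table()
    for el, r in table.radii.items():
        if abs(r - radius) < 1e-9 and len(el) <= 1:
            return el
    for el, r in table.radii.items():
        if abs(r - radius) < 1e-9:
            return el
    return "C"


def write_fixture(traj: Trajectory, spec: FixtureSpec, pdb_path, sidecar_path=None) -> None:
    """Write a fixture as multi-model PDB plus a JSON sidecar.

    Atom elements are chosen so the packaged radius table reproduces the
    fixture radii on re-read where possible; the sidecar also records the
    uniform radius for exact recovery.
    """
    from .structures_io import write_multimodel_pdb

    el = _element_for_radius(float(traj.frames[0].radii[0]))
    labels = [
        AtomLabel(element=el, atom_name=el, residue_name="FIX", residue_number=i + 1)
        for i in range(traj.n_atoms)
    ]
    write_multimodel_pdb(pdb_path, Trajectory(frames=traj.frames, atom_labels=labels))
    if sidecar_path is None:
        sidecar_path = str(pdb_path) + ".json" if not str(pdb_path).endswith(".pdb") else str(pdb_path)[:-4] + ".json"
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        fh.write(spec.to_json())
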