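"""Atomic structures, trajectories, van der Waals radii, and PDB input/output.

A trajectory is an ordered list of frames; every frame stores the same atoms
(same order, same radii) at time-dependent Cartesian coordinates in Å. Each
atom is modelled as a sphere with its van der Waals radius. Before any
Voronoi computation the coordinates are perturbed by a tiny random vector to
break exact degeneracies (cospherical or cocircular atom arrangements).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging
import warnings
from typing import Iterator, List, Optional, Sequence

import gemmi
import numpy as np

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Sphere:
    """A sphere in 3-space: ``center`` (Å, length-3) and ``radius`` (Å, > 0)."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float)
        object.__setattr__(self, "center", center)
        if center.shape != (3,) or not np.all(np.isfinite(center)):
            raise ValueError("center must be a finite 3-vector")
        if not self.radius > 0:
            raise ValueError("radius must be > 0")


@dataclasses.dataclass
class AtomLabel:
    """Identity of one atom index across the trajectory."""

    element: str = ""
    atom_name: str = ""
    residue_name: str = ""
    residue_number: int = 0
    chain: str = ""


@dataclasses.dataclass
class Frame:
    """One time step: coordinates ``coords`` (n, 3) and radii ``radii`` (n,), Å."""

    coords: np.ndarray
    radii: np.ndarray
    time_index: int = 0
    time_ps: Optional[float] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if self.radii.shape != (self.coords.shape[0],):
            raise ValueError("radii must have shape (n,)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if not np.all(self.radii > 0):
            raise ValueError("all radii must be > 0")
        if self.time_index < 0:
            raise ValueError("time_index must be >= 0")

    @property
    def n_spheres(self) -> int:
        return self.coords.shape[0]

    def sphere(self, i: int) -> Sphere:
        return Sphere(self.coords[i].copy(), float(self.radii[i]))

    @property
    def spheres(self) -> List[Sphere]:
        return [self.sphere(i) for i in range(self.n_spheres)]

    def bounding_box(self, margin: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned box of the atom sphere extents, expanded by ``margin``."""
        lo = (self.coords - self.radii[:, None]).min(axis=0) - margin
        hi = (self.coords + self.radii[:, None]).max(axis=0) + margin
        return lo, hi


@dataclasses.dataclass
class Trajectory:
    """Ordered frames with a shared atom list."""

    frames: List[Frame]
    atom_labels: List[AtomLabel] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = self.frames[0].n_spheres
        for f in self.frames:
            if f.n_spheres != n:
                raise ValueError("all frames must have equal sphere counts")
        idx = [f.time_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("time_index must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_spheres

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)


@dataclasses.dataclass
class RadiusTable:
    """Element symbol → van der Waals radius (Å), with a fallback radius."""

    radii: dict
    fallback: float = 1.50
    version: str = "1"

    def __post_init__(self) -> None:
        for el, r in self.radii.items():
            if not 0.5 < r < 3.0:
                raise ValueError(f"radius for {el} out of (0.5, 3.0) Å: {r}")
        if not 0.5 < self.fallback < 3.0:
            raise ValueError("fallback radius out of (0.5, 3.0) Å")

    def lookup(self, element: str, atom_name: str = "") -> float:
        """Radius for an element symbol, falling back to atom-name heuristics."""
        el = element.strip().upper()
        if el in self.radii:
            return self.radii[el]
        # Heuristic: strip digits from the atom name, try 2- then 1-letter key.
        name = "".join(ch for ch in atom_name.strip().upper() if ch.isalpha())
        if name[:2] in self.radii:
            return self.radii[name[:2]]
        if name[:1] in self.radii:
            return self.radii[name[:1]]
        warnings.warn(
            f"unknown element {element!r} (atom {atom_name!r}); "
            f"using fallback radius {self.fallback} Å"
        )
        return self.fallback


def load_default_radius_table() -> RadiusTable:
    """Load the packaged van der Waals radius table."""
    text = (
        importlib.resources.files("cavipath")
        .joinpath("data/vdw_radii.csv")
        .read_text(encoding="utf-8")
    )
    radii = {}
    version = "1"
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "version" in line:
                version = line.rsplit("version", 1)[-1].strip()
            continue
        el, r = line.split(",")
        radii[el.strip().upper()] = float(r)
    return RadiusTable(radii=radii, version=version)


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def read_multimodel_pdb(
    path,
    radii: Optional[RadiusTable] = None,
    exclude_residues: Sequence[str] = (),
    exclude_hydrogens: bool = False,
) -> Trajectory:
    """Read a multi-model PDB file as a trajectory, one frame per MODEL.

    Radii are assigned per atom from the element (PDB columns 77-78, falling
    back to atom-name heuristics and then to the table's fallback radius).
    Raises ``ValueError`` if the MODELs do not share one atom ordering.
    """
    radii = radii or load_default_radius_table()
    exclude = {r.strip().upper() for r in exclude_residues}
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models found in {path}")

    frames: List[Frame] = []
    labels: List[AtomLabel] = []
    signature0: Optional[list] = None
    radii_arr: Optional[np.ndarray] = None
    for m_i, model in enumerate(st):
        coords = []
        signature = []
        model_labels = []
        for chain in model:
            for res in chain:
                if res.name.strip().upper() in exclude:
                    continue
                for atom in res:
                    el = atom.element.name if atom.element else ""
                    if exclude_hydrogens and el.upper() in ("H", "D"):
                        continue
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    signature.append((chain.name, res.seqid.num, res.name, atom.name))
                    model_labels.append(
                        AtomLabel(
                            element=el,
                            atom_name=atom.name,
                            residue_name=res.name,
                            residue_number=res.seqid.num,
                            chain=chain.name,
                        )
                    )
        if signature0 is None:
            signature0 = signature
            labels = model_labels
            radii_arr = np.array(
                [radii.lookup(l.element, l.atom_name) for l in labels]
            )
        elif signature != signature0:
            raise ValueError(
                f"MODEL {m_i + 1} of {path} has a different atom list "
                f"({len(signature)} atoms vs {len(signature0)})"
            )
        frames.append(
            Frame(coords=np.array(coords), radii=radii_arr.copy(), time_index=m_i)
        )
    return Trajectory(frames=frames, atom_labels=labels)


def write_multimodel_pdb(path, trajectory: Trajectory) -> None:
    """Write a trajectory as a multi-model PDB file (one MODEL per frame)."""
    st = gemmi.Structure()
    st.name = "cavipath"
    labels = trajectory.atom_labels or [
        AtomLabel(element="C", atom_name="C", residue_name="UNK", residue_number=i + 1)
        for i in range(trajectory.n_atoms)
    ]
    for frame in trajectory.frames:
        model = gemmi.Model(str(frame.time_index + 1))
        chain_map = {}
        for i, lab in enumerate(labels):
            cname = lab.chain or "A"
            if cname not in chain_map:
                chain_map[cname] = gemmi.Chain(cname)
            chain = chain_map[cname]
            resnum = lab.residue_number or (i + 1)
            if (
                len(chain) == 0
                or chain[-1].seqid.num != resnum
                or chain[-1].name != (lab.residue_name or "UNK")
            ):
                res = gemmi.Residue()
                res.name = lab.residue_name or "UNK"
                res.seqid = gemmi.SeqId(resnum, " ")
                chain.add_residue(res)
            atom = gemmi.Atom()
            atom.name = lab.atom_name or (lab.element or "C")
            atom.element = gemmi.Element(lab.element or "C")
            x, y, z = frame.coords[i]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            chain[-1].add_atom(atom)
        for chain in chain_map.values():
            model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Plain-text sphere lists (fixture carrier format)
# ---------------------------------------------------------------------------

def read_xyzr(path) -> Frame:
    """Read a whitespace-separated ``x y z r`` sphere list as one frame."""
    data = np.loadtxt(path, dtype=float, ndmin=2)
    if data.shape[1] != 4:
        raise ValueError("xyzr file must have 4 columns")
    return Frame(coords=data[:, :3], radii=data[:, 3])


def write_xyzr(path, frame: Frame) -> None:
    data = np.column_stack([frame.coords, frame.radii])
    np.savetxt(path, data, fmt="%.6f")


# ---------------------------------------------------------------------------
# Degeneracy-breaking perturbation
# ---------------------------------------------------------------------------

def perturb_positions(frame: Frame, epsilon: float = 1e-6, seed: int = 0) -> Frame:
    """Displace every center by an independent random vector of length <= epsilon.

    Deterministic for a fixed seed; radii are unchanged. Directions are uniform
    on the sphere and lengths follow the uniform-ball distribution, so the
    displacement is uniform in the epsilon-ball.
    """
    if not epsilon > 0:
        raise ValueError("epsilon must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, frame.time_index]))
    n = frame.n_spheres
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    length = epsilon * rng.random(n) ** (1.0 / 3.0)
    return Frame(
        coords=frame.coords + direction * length[:, None],
        radii=frame.radii.copy(),
        time_index=frame.time_index,
        time_ps=frame.time_ps,
    )


def perturb_trajectory(traj: Trajectory, epsilon: float = 1e-6, seed: int = 0) -> Trajectory:
    """Apply :func:`perturb_positions` to every frame.

    Each frame's sub-seed is derived from ``(seed, time_index)`` so frames are
    independently reproducible.
    """
    return Trajectory(
        frames=[perturb_positions(f, epsilon=epsilon, seed=seed) for f in traj.frames],
        atom_labels=traj.atom_labels,
    )
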