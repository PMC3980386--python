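"""Run-time configuration and package-wide default parameters.

All lengths are in Angstrom (Å). The defaults reflect the standard operating
point for water-accessible cavity analysis: a probe sphere the size of a water
molecule (r_p = 1.4 Å), a 15 % ambient-light threshold for discarding Voronoi
elements outside the molecular domain, a 0.2 Å cube length for grid-based
volumes, and a minimal intersection-circle radius for time tracing equal to
the probe radius.
"""

from __future__ import annotations

import dataclasses
import pathlib
from typing import Optional, Sequence

import yaml

#: Probe-sphere radius used for path filtering, Å (water-sized probe).
DEFAULT_PROBE_RADIUS = 1.4
#: Ambient-light fraction above which a Voronoi vertex is considered outside
#: the molecule.
DEFAULT_OCCLUSION_THRESHOLD = 0.15
#: Number of ray directions for the ambient-occlusion estimate.
DEFAULT_N_RAYS = 256
#: Minimal intersection-circle radius for cavity correspondence between
#: consecutive frames, Å. Should equal or resemble the probe radius.
DEFAULT_MIN_INTERSECTION_RADIUS = 1.4
#: Cube side length for grid-based volume estimation, Å.
DEFAULT_CUBE_LENGTH = 0.2
#: Random perturbation magnitude applied to break degeneracies, Å.
DEFAULT_PERTURBATION = 1e-6
#: Margin added to the frame bounding box before clipping unbounded Voronoi
#: edges and exterior vertices, Å.
DEFAULT_BOUNDING_MARGIN = 5.0
#: Approximate volume of one water molecule, Å³ (used for capacity estimates).
WATER_VOLUME_A3 = 30.0
#: Above this sphere count, Voronoi vertex candidates come from the Delaunay
#: triangulation of the centers instead of exhaustive 4-subset enumeration.
DEFAULT_EXACT_ENUMERATION_LIMIT = 30


@dataclasses.dataclass
class RunConfig:
    """Parameters of a full preprocessing/tracing run."""

    input_path: Optional[str] = None
    output_dir: str = "cavipath_out"
    probe_radius: float = DEFAULT_PROBE_RADIUS
    occlusion_threshold: float = DEFAULT_OCCLUSION_THRESHOLD
    n_rays: int = DEFAULT_N_RAYS
    min_intersection_radius: float = DEFAULT_MIN_INTERSECTION_RADIUS
    cube_length: float = DEFAULT_CUBE_LENGTH
    perturbation: float = DEFAULT_PERTURBATION
    bounding_margin: float = DEFAULT_BOUNDING_MARGIN
    seed: int = 0
    frame_start: Optional[int] = None
    frame_stop: Optional[int] = None
    axis: Sequence[float] = (0.0, 0.0, 1.0)
    exclude_residues: Sequence[str] = ()

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if not 0.0 <= self.occlusion_threshold <= 1.0:
            raise ValueError("occlusion_threshold must be in [0, 1]")
        if self.cube_length <= 0:
            raise ValueError("cube_length must be > 0")

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["axis"] = list(self.axis)
        d["exclude_residues"] = list(self.exclude_residues)
        return d
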