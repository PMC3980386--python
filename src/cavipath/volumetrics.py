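"""Grid-based volumes of sphere unions and the inscribed intersection circle.

Exact volumes of unions of mutually intersecting spheres are notoriously
fiddly; instead, space is discretized into cubes of side ``a`` and the volume
of a cavity is the summed volume of all cubes whose centers lie strictly
inside at least one of its spheres. As ``a`` shrinks this converges to the
true union volume. Intersection volumes count cubes inside at least one
sphere of *each* cavity, over a shared grid restricted to the intersection of
the two bounding boxes.

The inscribed intersection circle of two spheres — the largest circle that
fits inside their intersection volume — is the primitive behind both the
edge-sphere placement criterion and the frame-to-frame cavity correspondence
test. With centers at distance ``d``:

* ``d >= r1 + r2``: the spheres are disjoint, no circle exists;
* ``d**2 <= |r1**2 - r2**2|``: the smaller sphere's great circle fits inside
  the larger sphere, so the answer is ``min(r1, r2)`` (this includes, but is
  wider than, full containment);
* otherwise the largest circle is the rim circle of the lens,
  ``sqrt(r1**2 - x**2)`` with ``x = (d**2 + r1**2 - r2**2) / (2 d)``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, TYPE_CHECKING

import numpy as np

from .config import WATER_VOLUME_A3
from .structures_io import Sphere

if TYPE_CHECKING:  # pragma: no cover
    from .cavity_model import Cavity


# ---------------------------------------------------------------------------
# Inscribed intersection circle
# ---------------------------------------------------------------------------

def largest_intersection_circle_radius(s1: Sphere, s2: Sphere) -> Optional[float]:
    """Radius of the largest circle inside the intersection of two spheres.

    Returns ``None`` when the spheres do not intersect.
    """
    d = float(np.linalg.norm(np.asarray(s1.center, float) - np.asarray(s2.center, float)))
    r1, r2 = float(s1.radius), float(s2.radius)
    if d >= r1 + r2:
        return None
    if d * d <= abs(r1 * r1 - r2 * r2):
        return min(r1, r2)
    x = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    return math.sqrt(max(r1 * r1 - x * x, 0.0))


def intersection_circle_radii(
    centers1: np.ndarray,
    radii1: np.ndarray,
    centers2: np.ndarray,
    radii2: np.ndarray,
) -> np.ndarray:
    """Vectorized all-pairs inscribed-circle radii; NaN where disjoint.

    Returns an array of shape ``(len(centers1), len(centers2))``.
    """
    c1 = np.asarray(centers1, float)
    c2 = np.asarray(centers2, float)
    r1 = np.asarray(radii1, float)[:, None]
    r2 = np.asarray(radii2, float)[None, :]
    d = np.linalg.norm(c1[:, None, :] - c2[None, :, :], axis=2)
    out = np.full(d.shape, np.nan)
    overlap = d < (r1 + r2)
    inner = d * d <= np.abs(r1 * r1 - r2 * r2)
    contain = overlap & inner
    out[contain] = np.broadcast_to(np.minimum(r1, r2), d.shape)[contain]
    rim = overlap & ~inner
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
        rr = np.sqrt(np.clip(np.broadcast_to(r1 * r1, d.shape) - x * x, 0.0, None))
    out[rim] = rr[rim]
    return out


# ---------------------------------------------------------------------------
# Volume grid
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VolumeGrid:
    """Regular cube sampling: cube centers at ``origin + (i + 1/2) * a``."""

    origin: np.ndarray
    spacing: float
    dims: tuple
    occupancy: np.ndarray  # bool or integer array of shape dims

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if not self.spacing > 0:
            raise ValueError("spacing must be > 0")
        self.dims = tuple(int(d) for d in self.dims)
        if self.occupancy.shape != self.dims:
            raise ValueError("occupancy shape must equal dims")

    def cube_centers_1d(self, axis: int) -> np.ndarray:
        i = np.arange(self.dims[axis])
        return self.origin[axis] + (i + 0.5) * self.spacing

    @property
    def cube_volume(self) -> float:
        return self.spacing ** 3


def _grid_dims(lo: np.ndarray, hi: np.ndarray, a: float) -> tuple:
    return tuple(max(int(np.ceil((hi[k] - lo[k]) / a)), 0) for k in range(3))


def occupancy_grid(
    centers: np.ndarray,
    radii: np.ndarray,
    origin: np.ndarray,
    dims: tuple,
    a: float,
) -> np.ndarray:
    """Boolean grid marking cubes whose center is strictly inside >= 1 sphere."""
    occ = np.zeros(dims, dtype=bool)
    if len(centers) == 0 or 0 in dims:
        return occ
    origin = np.asarray(origin, float)
    for c, r in zip(np.asarray(centers, float), np.asarray(radii, float)):
        # Index window of cubes the sphere can reach.
        lo_i = np.floor((c - r - origin) / a - 0.5).astype(int)
        hi_i = np.ceil((c + r - origin) / a - 0.5).astype(int)
        lo_i = np.maximum(lo_i, 0)
        hi_i = np.minimum(hi_i, np.array(dims) - 1)
        if np.any(hi_i < lo_i):
            continue
        xs = origin[0] + (np.arange(lo_i[0], hi_i[0] + 1) + 0.5) * a - c[0]
        ys = origin[1] + (np.arange(lo_i[1], hi_i[1] + 1) + 0.5) * a - c[1]
        zs = origin[2] + (np.arange(lo_i[2], hi_i[2] + 1) + 0.5) * a - c[2]
        d2 = (
            xs[:, None, None] ** 2
            + ys[None, :, None] ** 2
            + zs[None, None, :] ** 2
        )
        occ[
            lo_i[0] : hi_i[0] + 1,
            lo_i[1] : hi_i[1] + 1,
            lo_i[2] : hi_i[2] + 1,
        ] |= d2 < r * r
    return occ


def cavity_occupancy_grid(cavity: "Cavity", a: float) -> VolumeGrid:
    """Occupancy grid of a cavity over its own bounding box."""
    lo, hi = cavity.aabb
    dims = _grid_dims(lo, hi, a)
    occ = occupancy_grid(cavity.centers, cavity.radii, lo, dims, a)
    return VolumeGrid(origin=lo, spacing=a, dims=dims, occupancy=occ)


def cavity_volume(cavity: "Cavity", a: float) -> float:
    """Grid-estimated volume of the cavity's sphere union, Å³."""
    if not a > 0:
        raise ValueError("cube length a must be > 0")
    if len(cavity.centers) == 0:
        return 0.0
    grid = cavity_occupancy_grid(cavity, a)
    return float(np.count_nonzero(grid.occupancy)) * a ** 3


def cavity_intersection_volume(c1: "Cavity", c2: "Cavity", a: float) -> float:
    """Grid-estimated volume of the intersection of two cavities, Å³.

    The grid is restricted to the intersection of the two bounding boxes and
    shared by both operands, so the result is exactly symmetric. Spheres that
    do not reach the reduced box are ignored.
    """
    if not a > 0:
        raise ValueError("cube length a must be > 0")
    lo = np.maximum(c1.aabb[0], c2.aabb[0])
    hi = np.minimum(c1.aabb[1], c2.aabb[1])
    if np.any(hi <= lo):
        return 0.0
    dims = _grid_dims(lo, hi, a)
    if 0 in dims:
        return 0.0

    def _reduced(cav):
        if len(cav.centers) == 0:
            return cav.centers, cav.radii
        keep = np.all(
            (cav.centers + cav.radii[:, None] > lo)
            & (cav.centers - cav.radii[:, None] < hi),
            axis=1,
        )
        return cav.centers[keep], cav.radii[keep]

    cen1, rad1 = _reduced(c1)
    cen2, rad2 = _reduced(c2)
    occ1 = occupancy_grid(cen1, rad1, lo, dims, a)
    occ2 = occupancy_grid(cen2, rad2, lo, dims, a)
    return float(np.count_nonzero(occ1 & occ2)) * a ** 3


def water_capacity(volume: float) -> int:
    """How many water molecules fit in ``volume`` Å³ at ~30 Å³ per molecule."""
    if volume < 0:
        raise ValueError("volume must be >= 0")
    return int(math.floor(volume / WATER_VOLUME_A3))
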