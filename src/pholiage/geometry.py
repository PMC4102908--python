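"""3D scene geometry: ellipsoidal tree crown, vegetation slab, liberation gap.

The scene is a single target tree whose crown is an axisymmetric ellipsoid
(circular horizontal cross-section), embedded in a horizontally homogeneous
vegetation layer treated as a turbid medium.  A "liberation" gap is a vertical
cylinder of cleared vegetation centred on the stem, running from the soil to
the top of the vegetation.  The vegetation medium occupies the slab
``0 <= z <= H_veg`` minus the gap cylinder minus the crown ellipsoid, so no
volume is double-counted.

Coordinate frame: z points up, the ground is z = 0 and the stem of the target
tree sits at the horizontal origin unless placed elsewhere.  All lengths are
in metres; angles are degrees in user-facing APIs and radians internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LeafAngleDistribution",
    "TreeGeometry",
    "VegetationStand",
    "Gap",
    "Scene",
    "Ray",
    "build_tree",
    "ray_slab_path",
    "ray_ellipsoid_chord",
    "ray_cylinder_path",
    "vegetation_path_length",
    "media_path_lengths",
]

_SPHERICAL = "spherical"

# Printed leaf-angle tables are rounded to two decimals, so class fractions
# may sum to e.g. 1.01; accept that without renormalising.
_FRACTION_SUM_TOL = 0.02


@dataclass(frozen=True)
class LeafAngleDistribution:
    """Discrete leaf-inclination distribution with uniform leaf azimuth.

    ``fractions[i]`` is the fraction of leaf area whose inclination (angle of
    the leaf plane from horizontal) falls in the class with midpoint
    ``angles_deg[i]``.  The ``spherical`` preset stands for leaf normals
    distributed uniformly over the sphere, for which the projection function
    is exactly 1/2 at every beam elevation.
    """

    angles_deg: tuple[float, ...]
    fractions: tuple[float, ...]
    preset: str | None = None

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.angles_deg)
        fracs = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "angles_deg", angles)
        object.__setattr__(self, "fractions", fracs)
        if len(angles) != len(fracs) or not angles:
            raise ValueError("angles and fractions must be non-empty and equal length")
        if any(a < 0.0 or a > 90.0 for a in angles):
            raise ValueError("leaf inclination angles must lie in [0, 90] degrees")
        if any(f < 0.0 or f > 1.0 for f in fracs):
            raise ValueError("leaf-angle fractions must lie in [0, 1]")
        if self.preset is None and abs(sum(fracs) - 1.0) > _FRACTION_SUM_TOL:
            raise ValueError(
                f"leaf-angle fractions sum to {sum(fracs):.4f}, expected 1"
            )

    @classmethod
    def spherical(cls) -> "LeafAngleDistribution":
        """Leaf normals uniform on the sphere (projection exactly 1/2)."""
        return cls((57.3,), (1.0,), preset=_SPHERICAL)

    @classmethod
    def horizontal(cls) -> "LeafAngleDistribution":
        return cls((0.0,), (1.0,))

    @property
    def is_spherical(self) -> bool:
        return self.preset == _SPHERICAL


@dataclass(frozen=True)
class TreeGeometry:
    """Ellipsoidal crown on a stem: position, dimensions, foliage.

    Parameters
    ----------
    height : total tree height, ground to crown top (m).
    crown_length : vertical axis of the crown ellipsoid (m).
    crown_width : horizontal diameter of the crown (m); the cross-section is
        circular.
    leaf_area : total one-sided leaf area (m^2).
    lad : leaf area density inside the crown (m^2 m^-3).
    leaf_angles : leaf inclination distribution of the crown foliage.
    stem_xy : horizontal stem position (m).
    """

    height: float
    crown_length: float
    crown_width: float
    leaf_area: float
    lad: float
    leaf_angles: LeafAngleDistribution
    stem_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.crown_length, self.crown_width, self.leaf_area, self.lad) <= 0:
            raise ValueError("crown dimensions, leaf area and lad must be positive")
        if self.crown_base < -1e-12:
            raise ValueError("crown longer than tree height")
        ratio = self.leaf_area / (self.lad * self.crown_volume)
        if not (0.5 <= ratio <= 2.0):
            warnings.warn(
                f"leaf_area ({self.leaf_area} m^2) differs from lad*volume "
                f"({self.lad * self.crown_volume:.4g} m^2) by more than a factor 2",
                stacklevel=2,
            )

    @property
    def crown_base(self) -> float:
        return self.height - self.crown_length

    @property
    def crown_center_z(self) -> float:
        return self.crown_base + 0.5 * self.crown_length

    @property
    def crown_volume(self) -> float:
        return math.pi / 6.0 * self.crown_length * self.crown_width**2

    @property
    def semi_axes(self) -> tuple[float, float, float]:
        """(a, a, c): horizontal and vertical semi-axes of the ellipsoid."""
        a = 0.5 * self.crown_width
        return a, a, 0.5 * self.crown_length


def build_tree(
    height: float,
    crown_volume: float,
    lw_ratio: float,
    leaf_area: float,
    lad: float | None = None,
    leaf_angles: LeafAngleDistribution | None = None,
    stem_xy: tuple[float, float] = (0.0, 0.0),
) -> TreeGeometry:
    """Build a tree from volume and length:width ratio of its crown.

    Field allometry reports crown size as volume V and the length:width
    ratio rho, from which the axisymmetric ellipsoid is reconstructed:
    ``w = (6 V / (pi rho))^(1/3)`` and ``l = rho * w``.  ``lad`` defaults to
    ``leaf_area / V``.
    """
    if min(height, crown_volume, lw_ratio, leaf_area) <= 0:
        raise ValueError("height, crown_volume, lw_ratio and leaf_area must be > 0")
    w = (6.0 * crown_volume / (math.pi * lw_ratio)) ** (1.0 / 3.0)
    length = lw_ratio * w
    if length > height + 1e-12:
        raise ValueError("crown longer than tree height")
    if lad is None:
        lad = leaf_area / crown_volume
    if leaf_angles is None:
        leaf_angles = LeafAngleDistribution.spherical()
    return TreeGeometry(
        height=height,
        crown_length=length,
        crown_width=w,
        leaf_area=leaf_area,
        lad=lad,
        leaf_angles=leaf_angles,
        stem_xy=stem_xy,
    )


@dataclass(frozen=True)
class VegetationStand:
    """Surrounding vegetation as a homogeneous turbid slab.

    ``lai`` is the leaf area index (m^2 m^-2) and ``height`` the canopy top
    (m); the leaf area density of the slab is ``lai / height``.
    """

    height: float
    lai: float
    leaf_angles: LeafAngleDistribution = field(
        default_factory=LeafAngleDistribution.spherical
    )

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("stand height must be > 0")
        if self.lai < 0:
            raise ValueError("stand LAI must be >= 0")

    @property
    def lad_veg(self) -> float:
        return self.lai / self.height


@dataclass(frozen=True)
class Gap:
    """Vertical cylinder of cleared vegetation around the stem.

    The axis runs through the tree stem from the soil to the top of the
    surrounding vegetation.  ``radius = 0`` is the intact (control) canopy.
    """

    radius: float

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("gap radius must be >= 0")


@dataclass(frozen=True)
class Scene:
    """A target tree inside a vegetation stand with a liberation gap."""

    tree: TreeGeometry
    stand: VegetationStand
    gap: Gap = field(default_factory=lambda: Gap(0.0))


@dataclass(frozen=True)
class Ray:
    """Upward ray: origin plus unit direction with positive z component."""

    origin: tuple[float, float, float]
    direction: tuple[float, float, float]

    def __post_init__(self) -> None:
        o = tuple(float(v) for v in self.origin)
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if abs(n - 1.0) > 1e-9:
            d = d / n
        if d[2] <= 0:
            raise ValueError("ray direction must point upward (d_z > 0)")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", tuple(float(v) for v in d))

    @classmethod
    def from_angles(
        cls,
        origin: Sequence[float],
        elevation_deg: float,
        azimuth_deg: float = 0.0,
    ) -> "Ray":
        b = math.radians(elevation_deg)
        a = math.radians(azimuth_deg)
        d = (math.cos(b) * math.cos(a), math.cos(b) * math.sin(a), math.sin(b))
        return cls(tuple(float(v) for v in origin), d)


# ---------------------------------------------------------------------------
# Vectorised ray/solid interval arithmetic.  Each medium contributes a convex
# parameter interval [lo, hi] along the ray; empty intervals are (+inf, -inf).


def _slab_interval(oz: np.ndarray, dz: float, z_top: float):
    lo = (0.0 - oz) / dz
    hi = (z_top - oz) / dz
    return lo, hi


def _cylinder_interval(
    ox: np.ndarray, oy: np.ndarray, d: np.ndarray, cx: float, cy: float, radius: float
):
    """Interval of an infinite vertical cylinder |xy - c| <= radius."""
    n = np.shape(ox)
    lo = np.full(n, np.inf)
    hi = np.full(n, -np.inf)
    if radius <= 0.0:
        return lo, hi
    px = ox - cx
    py = oy - cy
    a = d[0] * d[0] + d[1] * d[1]
    if a < 1e-30:  # vertical ray: inside for all t or never
        inside = px * px + py * py <= radius * radius
        lo[inside] = -np.inf
        hi[inside] = np.inf
        return lo, hi
    b = px * d[0] + py * d[1]
    c = px * px + py * py - radius * radius
    disc = b * b - a * c
    hit = disc > 0.0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    lo = np.where(hit, (-b - sq) / a, np.inf)
    hi = np.where(hit, (-b + sq) / a, -np.inf)
    return lo, hi


def _ellipsoid_interval(o: np.ndarray, d: np.ndarray, tree: TreeGeometry):
    """Interval inside the crown ellipsoid, in normalised coordinates."""
    a, _, c = tree.semi_axes
    if a <= 0 or c <= 0:
        raise ValueError("degenerate crown ellipsoid axes")
    px = (o[..., 0] - tree.stem_xy[0]) / a
    py = (o[..., 1] - tree.stem_xy[1]) / a
    pz = (o[..., 2] - tree.crown_center_z) / c
    dx, dy, dz = d[0] / a, d[1] / a, d[2] / c
    A = dx * dx + dy * dy + dz * dz
    B = px * dx + py * dy + pz * dz
    C = px * px + py * py + pz * pz - 1.0
    disc = B * B - A * C
    hit = disc > 0.0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    lo = np.where(hit, (-B - sq) / A, np.inf)
    hi = np.where(hit, (-B + sq) / A, -np.inf)
    return lo, hi


def _length(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Length of [lo, hi] clipped to the forward half-line t >= 0."""
    return np.maximum(0.0, hi - np.maximum(lo, 0.0))


def media_path_lengths(points: np.ndarray, direction: Sequence[float], scene: Scene):
    """Path lengths through vegetation and crown for rays from many points.

    Parameters
    ----------
    points : (N, 3) ray origins.
    direction : shared unit direction with positive z component.
    scene : the scene whose media are traversed.

    Returns
    -------
    (s_veg, s_crown) : two (N,) arrays.  ``s_veg`` is the path through the
    vegetation medium (slab minus gap minus crown, by inclusion–exclusion);
    ``s_crown`` is the full forward chord through the crown ellipsoid,
    including any part protruding above the slab.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.asarray(direction, dtype=float)
    if d[2] <= 0:
        raise ValueError("direction must point upward")
    oz = pts[:, 2]
    s_lo, s_hi = _slab_interval(oz, d[2], scene.stand.height)
    g_lo, g_hi = _cylinder_interval(
        pts[:, 0], pts[:, 1], d,
        scene.tree.stem_xy[0], scene.tree.stem_xy[1], scene.gap.radius,
    )
    e_lo, e_hi = _ellipsoid_interval(pts, d, scene.tree)

    s_crown = _length(e_lo, e_hi)

    sg_lo, sg_hi = np.maximum(s_lo, g_lo), np.minimum(s_hi, g_hi)
    se_lo, se_hi = np.maximum(s_lo, e_lo), np.minimum(s_hi, e_hi)
    sge_lo, sge_hi = np.maximum(sg_lo, e_lo), np.minimum(sg_hi, e_hi)

    s_veg = (
        _length(s_lo, s_hi)
        - _length(sg_lo, sg_hi)
        - _length(se_lo, se_hi)
        + _length(sge_lo, sge_hi)
    )
    return np.maximum(s_veg, 0.0), s_crown


# ---------------------------------------------------------------------------
# Scalar convenience operations.


def ray_slab_path(ray: Ray, z_top: float) -> float:
    """Forward path length of the ray inside the slab 0 <= z <= z_top."""
    if z_top <= 0:
        raise ValueError("z_top must be > 0")
    oz = np.array([ray.origin[2]])
    lo, hi = _slab_interval(oz, ray.direction[2], z_top)
    return float(_length(lo, hi)[0])


def ray_ellipsoid_chord(ray: Ray, tree: TreeGeometry) -> float:
    """Forward path length of the ray inside the crown ellipsoid."""
    o = np.array([ray.origin], dtype=float)
    lo, hi = _ellipsoid_interval(o, np.asarray(ray.direction), tree)
    return float(_length(lo, hi)[0])


def ray_cylinder_path(
    ray: Ray,
    gap: Gap,
    z_top: float,
    axis_xy: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Forward path inside the gap cylinder, clipped to 0 <= z <= z_top."""
    o = np.array([ray.origin], dtype=float)
    d = np.asarray(ray.direction)
    c_lo, c_hi = _cylinder_interval(
        o[:, 0], o[:, 1], d, axis_xy[0], axis_xy[1], gap.radius
    )
    s_lo, s_hi = _slab_interval(o[:, 2], d[2], z_top)
    return float(_length(np.maximum(c_lo, s_lo), np.minimum(c_hi, s_hi))[0])


def vegetation_path_length(
    point: Sequence[float], direction: Sequence[float], scene: Scene
) -> float:
    """Forward path through the vegetation medium from a point.

    The vegetation occupies the slab minus the gap cylinder minus the crown
    ellipsoid; the result is never negative and never exceeds the slab path.
    """
    s_veg, _ = media_path_lengths(np.array([point], dtype=float), direction, scene)
    return float(s_veg[0])
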