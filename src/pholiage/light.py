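"""Discretised-sky ray tracing through the scene's turbid media.

Diffuse light from an overcast hemisphere is discretised into sky sectors of
equal solid angle.  For every sector the beam is attenuated along its path by
Beer's law with an extinction coefficient set by the leaf-angle projection
function (G-function) and the leaf area density of each medium traversed.
Leaves are black (fully absorbing) by default; an absorptance multiplier can
scale both extinction and capture.

Whole-crown light capture Phi (μmol photons s^-1) integrates the absorbed
photon flux density per unit leaf area over the crown volume times the leaf
area density; Phi_area = Phi / leaf_area is the size-corrected rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss

from .geometry import LeafAngleDistribution, Scene, TreeGeometry, media_path_lengths

__all__ = [
    "SkyModel",
    "PointLight",
    "CrownQuadrature",
    "LightCapture",
    "build_sky",
    "projection_single",
    "g_function",
    "beam_transmittance",
    "point_absorbed_ppfd",
    "crown_quadrature",
    "point_fluxes",
    "crown_light_capture",
]

DEFAULT_SKY_RESOLUTION = (9, 12)
DEFAULT_CROWN_RESOLUTION = (16, 16, 16)


@dataclass(frozen=True)
class SkyModel:
    """Discretised overcast hemisphere.

    ``beam[s]`` is the irradiance of sector ``s`` on a plane normal to its
    beam (μmol m^-2 s^-1); the sectors satisfy
    ``sum(beam * sin(elevation)) == i_o``, the horizontal photon flux density
    above the canopy.
    """

    elevation: np.ndarray  # radians, shape (S,)
    azimuth: np.ndarray  # radians, shape (S,)
    beam: np.ndarray  # μmol m^-2 s^-1, shape (S,)
    i_o: float
    sky_type: str

    @property
    def directions(self) -> np.ndarray:
        """(S, 3) unit vectors pointing from the scene toward each sector."""
        ce = np.cos(self.elevation)
        return np.column_stack(
            (ce * np.cos(self.azimuth), ce * np.sin(self.azimuth), np.sin(self.elevation))
        )


@dataclass(frozen=True)
class PointLight:
    """Absorbed PPFD at a crown point and its relative light intensity.

    ``rel_light`` is referenced to an unshaded leaf with the same leaf-angle
    distribution under the same sky, so a fully exposed crown top has
    ``rel_light == 1``.
    """

    phi_p: float
    rel_light: float


@dataclass(frozen=True)
class CrownQuadrature:
    """Weighted sample points filling the crown ellipsoid (weights in m^3)."""

    points: np.ndarray  # (N, 3)
    weights: np.ndarray  # (N,)


@dataclass(frozen=True)
class LightCapture:
    """Whole-crown light capture and its per-leaf-area normalisation."""

    phi: float  # μmol photons s^-1
    phi_area: float  # μmol photons m^-2 s^-1
    phi_top: float  # unshaded absorbed PPFD for this leaf-angle distribution


def build_sky(
    n_elevation: int = DEFAULT_SKY_RESOLUTION[0],
    n_azimuth: int = DEFAULT_SKY_RESOLUTION[1],
    sky_type: str = "uoc",
    i_o: float = 1000.0,
) -> SkyModel:
    """Discretise an overcast sky into equal-solid-angle sectors.

    Elevation bands are uniform in sin(beta) (equal solid angle), evaluated
    at band midpoints, so the horizon (beta = 0) is never sampled.  Radiance
    is constant for the uniform overcast sky ("uoc") and proportional to
    (1 + 2 sin beta)/3 for the standard overcast sky ("soc").  Sector beams
    are scaled so that the horizontal irradiance equals ``i_o``.
    """
    if n_elevation < 1 or n_azimuth < 1:
        raise ValueError("n_elevation and n_azimuth must be >= 1")
    if i_o < 0:
        raise ValueError("i_o must be >= 0")
    sky_type = sky_type.lower()
    if sky_type not in ("uoc", "soc"):
        raise ValueError(f"unknown sky_type {sky_type!r}; use 'uoc' or 'soc'")

    sin_beta = (np.arange(n_elevation) + 0.5) / n_elevation
    beta = np.arcsin(sin_beta)
    azim = (np.arange(n_azimuth) + 0.5) * 2.0 * math.pi / n_azimuth
    omega = 2.0 * math.pi / (n_azimuth * n_elevation)  # sector solid angle

    if sky_type == "uoc":
        radiance = np.ones_like(beta)
    else:
        radiance = (1.0 + 2.0 * sin_beta) / 3.0

    el = np.repeat(beta, n_azimuth)
    az = np.tile(azim, n_elevation)
    b = np.repeat(radiance, n_azimuth) * omega
    horiz = float(np.sum(b * np.sin(el)))
    if horiz > 0:
        b = b * (i_o / horiz)
    return SkyModel(elevation=el, azimuth=az, beam=b, i_o=float(i_o), sky_type=sky_type)


def projection_single(leaf_inclination_deg: float, beam_elevation_deg) -> np.ndarray | float:
    """Projection G of a single leaf-inclination class onto a beam.

    Mean |cos| of the angle between the leaf normal and the beam over
    uniform leaf azimuth, for leaves inclined ``alpha`` from horizontal and a
    beam at elevation ``beta``:

        G = cos(alpha) sin(beta)                          if beta >= alpha
        G = (2/pi) [sin(beta) cos(alpha) arcsin(tan beta / tan alpha)
                    + sqrt(sin^2 alpha - sin^2 beta)]     otherwise
    """
    a = math.radians(float(leaf_inclination_deg))
    beta = np.asarray(beam_elevation_deg, dtype=float)
    scalar = beta.ndim == 0
    b = np.atleast_1d(np.radians(beta))
    if np.any((b <= 0) | (b > math.pi / 2 + 1e-12)):
        raise ValueError("beam elevation must lie in (0, 90] degrees")
    sb, cb = np.sin(b), np.cos(b)
    sa, ca = math.sin(a), math.cos(a)
    out = ca * sb
    below = b < a - 1e-12
    if np.any(below):
        tb = np.tan(b[below])
        ta = math.tan(a)
        x = np.clip(tb / ta, -1.0, 1.0)
        out[below] = (2.0 / math.pi) * (
            sb[below] * ca * np.arcsin(x)
            + np.sqrt(np.maximum(sa * sa - sb[below] ** 2, 0.0))
        )
    return float(out[0]) if scalar else out


def g_function(leaf_angles: LeafAngleDistribution, beam_elevation_deg) -> np.ndarray | float:
    """G-function of a discrete leaf-angle distribution at beam elevation."""
    if leaf_angles.is_spherical:
        beta = np.asarray(beam_elevation_deg, dtype=float)
        return 0.5 if beta.ndim == 0 else np.full(beta.shape, 0.5)
    parts = [
        f * np.asarray(projection_single(a, beam_elevation_deg))
        for a, f in zip(leaf_angles.angles_deg, leaf_angles.fractions)
    ]
    total = sum(parts)
    return float(total) if np.ndim(total) == 0 else total


def beam_transmittance(
    point, direction, scene: Scene, absorptance: float = 1.0
) -> float:
    """Beer-law transmittance along an upward ray from a point.

    ``T = exp(-a [G_veg lad_veg s_veg + G_tree lad_tree s_crown])`` with the
    two path lengths from the scene geometry and ``a`` the leaf absorptance
    (1 for black leaves).
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    beta = math.degrees(math.asin(min(1.0, max(-1.0, d[2]))))
    s_veg, s_crown = media_path_lengths(np.array([point], dtype=float), d, scene)
    g_veg = g_function(scene.stand.leaf_angles, beta)
    g_tree = g_function(scene.tree.leaf_angles, beta)
    tau = g_veg * scene.stand.lad_veg * s_veg[0] + g_tree * scene.tree.lad * s_crown[0]
    return float(np.exp(-absorptance * tau))


def crown_quadrature(
    tree: TreeGeometry, resolution=DEFAULT_CROWN_RESOLUTION
) -> CrownQuadrature:
    """Product Gauss quadrature over the crown ellipsoid.

    Spherical-product rule in normalised coordinates: Gauss–Legendre nodes in
    the radial measure u = r^3 and in the polar cosine, midpoint nodes in
    azimuth.  Weights sum to the ellipsoid volume exactly (to rounding), and
    every node lies strictly inside the ellipsoid.
    """
    if isinstance(resolution, int):
        resolution = (resolution, resolution, resolution)
    n_r, n_mu, n_phi = resolution
    if min(n_r, n_mu, n_phi) < 2:
        raise ValueError("resolution must be >= 2 per axis")

    xu, wu = leggauss(n_r)
    u = 0.5 * (xu + 1.0)  # radial measure on (0, 1)
    wu = 0.5 * wu
    mu, wmu = leggauss(n_mu)  # polar cosine on (-1, 1)
    phi = (np.arange(n_phi) + 0.5) * 2.0 * math.pi / n_phi
    wphi = 2.0 * math.pi / n_phi

    r = u ** (1.0 / 3.0)
    st = np.sqrt(1.0 - mu * mu)

    R, MU, PHI = np.meshgrid(r, mu, phi, indexing="ij")
    ST = np.sqrt(1.0 - MU * MU)
    W = (
        wu[:, None, None]
        * wmu[None, :, None]
        * wphi
        / 3.0
    ) * np.ones_like(PHI)

    a, _, c = tree.semi_axes
    x = a * R * ST * np.cos(PHI) + tree.stem_xy[0]
    y = a * R * ST * np.sin(PHI) + tree.stem_xy[1]
    z = c * R * MU + tree.crown_center_z
    pts = np.column_stack((x.ravel(), y.ravel(), z.ravel()))
    w = (W * (a * a * c)).ravel()
    return CrownQuadrature(points=pts, weights=w)


def point_fluxes(
    points: np.ndarray, scene: Scene, sky: SkyModel, absorptance: float = 1.0
):
    """Absorbed PPFD per unit leaf area at many crown points.

    Returns ``(phi_p, phi_top)``: the (N,) array of absorbed photon flux
    densities and the unshaded value for the crown's leaf-angle distribution
    under the same sky.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    phi_p = np.zeros(pts.shape[0])
    phi_top = 0.0
    dirs = sky.directions
    beta_deg = np.degrees(sky.elevation)
    g_tree = np.atleast_1d(g_function(scene.tree.leaf_angles, beta_deg))
    g_veg = np.atleast_1d(g_function(scene.stand.leaf_angles, beta_deg))
    lad_veg = scene.stand.lad_veg
    lad_tree = scene.tree.lad
    for s in range(len(sky.beam)):
        s_veg, s_crown = media_path_lengths(pts, dirs[s], scene)
        tau = g_veg[s] * lad_veg * s_veg + g_tree[s] * lad_tree * s_crown
        phi_p += sky.beam[s] * g_tree[s] * absorptance * np.exp(-absorptance * tau)
        phi_top += sky.beam[s] * g_tree[s] * absorptance
    return phi_p, float(phi_top)


def point_absorbed_ppfd(
    point, scene: Scene, sky: SkyModel, absorptance: float = 1.0
) -> PointLight:
    """Absorbed PPFD and relative light intensity at one crown point."""
    phi_p, phi_top = point_fluxes(np.array([point], dtype=float), scene, sky, absorptance)
    rel = float(phi_p[0] / phi_top) if phi_top > 0 else 0.0
    return PointLight(phi_p=float(phi_p[0]), rel_light=rel)


def crown_light_capture(
    scene: Scene,
    sky: SkyModel,
    grid: CrownQuadrature | None = None,
    absorptance: float = 1.0,
) -> LightCapture:
    """Whole-crown light capture Phi and per-leaf-area Phi_area.

    ``Phi = sum_p weight_p * lad * phi_p`` over the crown quadrature.
    """
    if grid is None:
        grid = crown_quadrature(scene.tree)
    phi_p, phi_top = point_fluxes(grid.points, scene, sky, absorptance)
    phi = float(np.sum(grid.weights * scene.tree.lad * phi_p))
    return LightCapture(
        phi=phi, phi_area=phi / scene.tree.leaf_area, phi_top=phi_top
    )
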