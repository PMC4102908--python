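"""Leaf physiology and whole-crown net photosynthesis.

Leaf nitrogen per area declines from the crown top downwards with the light
gradient, ``N_area = N_o * (I/I_o)^0.4``, and the light-saturated gross rate
is proportional to nitrogen, ``P_max = slope * N_area``.  The leaf light
response is a non-rectangular hyperbola with curvature ``theta`` (default
0.7); net rate is gross minus dark respiration ``R_d``.  Crown totals
integrate the point rates over the crown quadrature, exactly as light
capture does.

Nitrogen acclimates over weeks, not seconds, so the gradient follows the
light climate the leaves grew in: by default the intact canopy (gap radius
0) of the same stand.  Opening a liberation gap therefore changes the
absorbed light instantaneously but not the nitrogen profile.

Units: PPFD in μmol photons m^-2 s^-1, rates in μmol CO2 m^-2 s^-1 (leaf) or
μmol CO2 s^-1 (crown), nitrogen in mmol N m^-2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Gap, Scene
from .light import CrownQuadrature, SkyModel, crown_quadrature, point_fluxes

__all__ = [
    "SpeciesPhysiology",
    "CrownResult",
    "NITROGEN_LIGHT_EXPONENT",
    "nitrogen_at",
    "pmax_at",
    "leaf_net_photosynthesis",
    "acclimated_relative_light",
    "crown_photosynthesis",
]

#: Exponent linking the relative light gradient to the nitrogen gradient.
NITROGEN_LIGHT_EXPONENT = 0.4


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Leaf physiological parameters of a species.

    Parameters
    ----------
    n_o : nitrogen per area of the most illuminated (crown-top) leaves
        (mmol N m^-2).
    pmax_slope : slope of the P_max–N_area relation
        (μmol CO2 m^-2 s^-1 per mmol N m^-2).
    r_d : dark respiration (μmol CO2 m^-2 s^-1).
    quantum_yield : apparent quantum yield on absorbed PPFD
        (mol CO2 mol photons^-1).
    theta : curvature of the non-rectangular hyperbola (0 = rectangular
        hyperbola, 1 = Blackman response).
    pmax_intercept : optional intercept of the P_max–N_area relation
        (μmol CO2 m^-2 s^-1); the default relation is proportional.
    """

    n_o: float
    pmax_slope: float
    r_d: float
    quantum_yield: float
    theta: float = 0.7
    pmax_intercept: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_o <= 0 or self.pmax_slope <= 0 or self.quantum_yield <= 0:
            raise ValueError("n_o, pmax_slope and quantum_yield must be > 0")
        if self.r_d < 0:
            raise ValueError("r_d must be >= 0")
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must lie in [0, 1]")


@dataclass(frozen=True)
class CrownResult:
    """Whole-crown light capture and net photosynthesis.

    ``phi_area`` and ``p_area`` are the whole-crown rates divided by leaf
    area, correcting for plant size.
    """

    phi: float  # μmol photons s^-1
    p: float  # μmol CO2 s^-1
    phi_area: float  # μmol photons m^-2 s^-1
    p_area: float  # μmol CO2 m^-2 s^-1
    leaf_area: float  # m^2


def nitrogen_at(rel_light, n_o: float):
    """Leaf nitrogen per area at relative light ``I/I_o`` in the crown."""
    rel = np.asarray(rel_light, dtype=float)
    if np.any(rel < 0):
        raise ValueError("rel_light must be >= 0")
    out = n_o * rel**NITROGEN_LIGHT_EXPONENT
    return float(out) if out.ndim == 0 else out


def pmax_at(n_area, pmax_slope: float, intercept: float = 0.0):
    """Light-saturated gross photosynthesis from leaf nitrogen per area."""
    n = np.asarray(n_area, dtype=float)
    if np.any(n < 0):
        raise ValueError("n_area must be >= 0")
    out = np.maximum(pmax_slope * n + intercept, 0.0)
    return float(out) if out.ndim == 0 else out


def leaf_net_photosynthesis(phi_p, p_max, quantum_yield: float, theta: float, r_d: float):
    """Net leaf photosynthesis from absorbed PPFD.

    Gross rate is the smaller root of the non-rectangular hyperbola
    ``theta P^2 - (q I + P_max) P + q I P_max = 0`` with ``q`` the quantum
    yield and ``I`` the absorbed PPFD; ``theta -> 0`` recovers the
    rectangular hyperbola and ``theta = 1`` the Blackman limit
    ``min(q I, P_max)``.  Net rate is gross minus ``r_d``.
    """
    i = quantum_yield * np.asarray(phi_p, dtype=float)
    if np.any(i < 0):
        raise ValueError("phi_p must be >= 0")
    pm = np.asarray(p_max, dtype=float)
    if theta < 1e-12:
        denom = i + pm
        gross = np.where(denom > 0, i * pm / np.where(denom > 0, denom, 1.0), 0.0)
    elif theta > 1.0 - 1e-12:
        gross = np.minimum(i, pm)
    else:
        b = i + pm
        disc = b * b - 4.0 * theta * i * pm
        gross = (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * theta)
    out = gross - r_d
    return float(out) if out.ndim == 0 else out


def acclimated_relative_light(
    scene: Scene,
    sky: SkyModel,
    grid: CrownQuadrature,
    absorptance: float = 1.0,
) -> np.ndarray:
    """Relative light intensity of the intact canopy at the grid points.

    The nitrogen gradient follows the light climate the leaves developed
    under, i.e. the same stand with gap radius 0 (for a gap-free scene this
    is the scene itself).
    """
    intact = scene if scene.gap.radius == 0.0 else Scene(
        tree=scene.tree, stand=scene.stand, gap=Gap(0.0)
    )
    phi_p, phi_top = point_fluxes(grid.points, intact, sky, absorptance)
    if phi_top <= 0:
        return np.zeros_like(phi_p)
    return phi_p / phi_top


def crown_photosynthesis(
    scene: Scene,
    physiology: SpeciesPhysiology,
    sky: SkyModel,
    grid: CrownQuadrature | None = None,
    absorptance: float = 1.0,
    acclimation_rel_light: np.ndarray | None = None,
) -> CrownResult:
    """Whole-crown light capture and net photosynthesis.

    For each quadrature point the relative light of the intact canopy sets
    the local nitrogen, hence the local ``P_max``; the point's absorbed PPFD
    in the actual (possibly liberated) scene then sets its net rate.  Crown
    totals are volume-weighted sums times the leaf area density.

    ``acclimation_rel_light`` overrides the per-point relative light used
    for the nitrogen gradient (e.g. a cached intact-canopy profile when
    sweeping gap radii).
    """
    tree = scene.tree
    if grid is None:
        grid = crown_quadrature(tree)
    phi_p, phi_top = point_fluxes(grid.points, scene, sky, absorptance)
    if acclimation_rel_light is None:
        if scene.gap.radius == 0.0:
            rel = phi_p / phi_top if phi_top > 0 else np.zeros_like(phi_p)
        else:
            rel = acclimated_relative_light(scene, sky, grid, absorptance)
    else:
        rel = np.asarray(acclimation_rel_light, dtype=float)
    n_area = nitrogen_at(rel, physiology.n_o)
    p_max = pmax_at(n_area, physiology.pmax_slope, physiology.pmax_intercept)
    net = leaf_net_photosynthesis(
        phi_p, p_max, physiology.quantum_yield, physiology.theta, physiology.r_d
    )
    w = grid.weights * tree.lad
    phi = float(np.sum(w * phi_p))
    p = float(np.sum(w * net))
    return CrownResult(
        phi=phi,
        p=p,
        phi_area=phi / tree.leaf_area,
        p_area=p / tree.leaf_area,
        leaf_area=tree.leaf_area,
    )
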