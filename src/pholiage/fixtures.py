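"""Packaged parameter tables and a seeded synthetic-scene generator.

The species and stand records transcribe the field study's summary tables
verbatim (group means and standard errors from a 1.5-year-old secondary
forest stand in central Vietnam): three pioneer Euphorbiaceae —
*Mallotus microcarpus*, *Mallotus paniculatus* and *Macaranga denticulata* —
and the three successional vegetation stands in which liberation was
simulated.  Standard errors are stored but the deterministic model consumes
only the means; biomass columns are metadata.

Dark respiration is stored in μmol CO2 m^-2 s^-1 (the printed table's
"mmol" column header is a unit typo at these magnitudes), and leaf nitrogen
in mmol N m^-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    Gap,
    LeafAngleDistribution,
    Scene,
    TreeGeometry,
    VegetationStand,
    build_tree,
)
from .photosynthesis import SpeciesPhysiology

__all__ = [
    "SpeciesFixture",
    "StandFixture",
    "GrowthObservation",
    "LEAF_ANGLE_CLASSES",
    "species_table2",
    "stands_table1",
    "growth_table3",
    "relative_reduction",
    "make_tree",
    "make_physiology",
    "random_scene",
]

#: Midpoint inclination angles (degrees) of the measured leaf-angle classes.
LEAF_ANGLE_CLASSES = (15.0, 45.0, 75.0)


@dataclass(frozen=True)
class SpeciesFixture:
    """Mean (± SE) characteristics of one species in the 1.5 y/o stand."""

    name: str
    height: float  # m
    height_se: float
    biomass: float  # g, metadata only
    biomass_se: float
    leaf_area: float  # m^2
    leaf_area_se: float
    leaf_angle_fractions: tuple[float, float, float]  # at 15/45/75 degrees
    crown_volume: float  # m^3
    crown_volume_se: float
    lw_ratio: float  # crown length : width
    lw_ratio_se: float
    lad: float  # m^2 m^-3
    lad_se: float
    n_o: float  # mmol N m^-2
    n_o_se: float
    pmax_slope: float  # μmol CO2 m^-2 s^-1 per mmol N m^-2
    pmax_slope_se: float
    r_d: float  # μmol CO2 m^-2 s^-1
    r_d_se: float
    quantum_yield: float  # mol CO2 mol photons^-1
    quantum_yield_se: float


@dataclass(frozen=True)
class StandFixture:
    """Mean (± SE) LAI and height of a successional vegetation stand."""

    label: str
    age_years: float
    lai: float
    lai_se: float
    height: float
    height_se: float

    @property
    def lad_veg(self) -> float:
        return self.lai / self.height


@dataclass(frozen=True)
class GrowthObservation:
    """Mean growth of liberated or control trees, 174 days after liberation."""

    species: str
    treatment: str  # "liberated" | "control"
    mean_height_cm: float
    mean_height_se: float
    height_growth_cm_day: float
    height_growth_se: float
    mean_biomass_g: float
    mean_biomass_se: float
    biomass_growth_g_day: float
    biomass_growth_se: float


_SPECIES = (
    SpeciesFixture(
        name="Mallotus microcarpus",
        height=1.26, height_se=0.07,
        biomass=52.70, biomass_se=8.48,
        leaf_area=0.29, leaf_area_se=0.02,
        leaf_angle_fractions=(0.23, 0.48, 0.29),
        crown_volume=0.04, crown_volume_se=0.00,
        lw_ratio=1.18, lw_ratio_se=0.03,
        lad=6.72, lad_se=0.27,
        n_o=94.28, n_o_se=1.25,
        pmax_slope=0.17, pmax_slope_se=0.05,
        r_d=1.04, r_d_se=0.02,
        quantum_yield=0.03, quantum_yield_se=0.00,
    ),
    SpeciesFixture(
        name="Mallotus paniculatus",
        height=0.94, height_se=0.01,
        biomass=12.22, biomass_se=0.56,
        leaf_area=0.06, leaf_area_se=0.00,
        leaf_angle_fractions=(0.13, 0.41, 0.46),
        crown_volume=0.01, crown_volume_se=0.00,
        lw_ratio=2.00, lw_ratio_se=0.03,
        lad=4.94, lad_se=0.15,
        n_o=79.33, n_o_se=0.84,
        pmax_slope=0.10, pmax_slope_se=0.05,
        r_d=0.24, r_d_se=0.01,
        quantum_yield=0.03, quantum_yield_se=0.00,
    ),
    SpeciesFixture(
        name="Macaranga denticulata",
        height=1.07, height_se=0.03,
        biomass=27.22, biomass_se=1.17,
        leaf_area=0.11, leaf_area_se=0.00,
        leaf_angle_fractions=(0.37, 0.40, 0.24),
        crown_volume=0.03, crown_volume_se=0.00,
        lw_ratio=1.42, lw_ratio_se=0.02,
        lad=4.35, lad_se=0.15,
        n_o=82.52, n_o_se=0.72,
        pmax_slope=0.18, pmax_slope_se=0.06,
        r_d=0.53, r_d_se=0.01,
        quantum_yield=0.04, quantum_yield_se=0.00,
    ),
)

_STANDS = (
    StandFixture(label="I", age_years=0.5, lai=3.03, lai_se=1.74, height=0.61, height_se=0.18),
    StandFixture(label="II", age_years=1.0, lai=5.46, lai_se=0.91, height=0.99, height_se=0.31),
    StandFixture(label="III", age_years=1.5, lai=3.73, lai_se=0.75, height=1.40, height_se=0.41),
)

_GROWTH = (
    GrowthObservation("Mallotus microcarpus", "liberated", 180.00, 9.51, 0.31, 0.01, 121.41, 12.00, 0.35, 0.03),
    GrowthObservation("Mallotus microcarpus", "control", 184.82, 9.27, 0.41, 0.02, 93.56, 13.79, 0.28, 0.04),
    GrowthObservation("Mallotus paniculatus", "liberated", 121.00, 1.58, 0.19, 0.01, 56.26, 4.46, 0.25, 0.02),
    GrowthObservation("Mallotus paniculatus", "control", 139.13, 2.07, 0.28, 0.01, 41.12, 2.26, 0.17, 0.01),
    GrowthObservation("Macaranga denticulata", "liberated", 133.14, 3.13, 0.16, 0.01, 68.57, 3.79, 0.25, 0.02),
    GrowthObservation("Macaranga denticulata", "control", 153.65, 2.72, 0.26, 0.00, 54.97, 2.87, 0.16, 0.01),
)


def species_table2() -> tuple[SpeciesFixture, ...]:
    """Mean species characteristics in the 1.5 y/o stand."""
    return _SPECIES


def stands_table1() -> tuple[StandFixture, ...]:
    """The three successional vegetation stands (0.5, 1 and 1.5 years)."""
    return _STANDS


def growth_table3() -> tuple[GrowthObservation, ...]:
    """Growth of liberated vs control trees 174 days after liberation."""
    return _GROWTH


def relative_reduction(metric: str = "height_growth") -> dict[str, float]:
    """(control - liberated)/control per species for a growth metric.

    ``metric`` is ``"height_growth"`` or ``"biomass_growth"``.
    """
    attr = {
        "height_growth": "height_growth_cm_day",
        "biomass_growth": "biomass_growth_g_day",
    }[metric]
    by_species: dict[str, dict[str, float]] = {}
    for obs in _GROWTH:
        by_species.setdefault(obs.species, {})[obs.treatment] = getattr(obs, attr)
    return {
        sp: (v["control"] - v["liberated"]) / v["control"]
        for sp, v in by_species.items()
    }


def make_tree(fix: SpeciesFixture, stem_xy: tuple[float, float] = (0.0, 0.0)) -> TreeGeometry:
    """Tree geometry from a species record (tabulated lad, raw fractions)."""
    return build_tree(
        height=fix.height,
        crown_volume=fix.crown_volume,
        lw_ratio=fix.lw_ratio,
        leaf_area=fix.leaf_area,
        lad=fix.lad,
        leaf_angles=LeafAngleDistribution(LEAF_ANGLE_CLASSES, fix.leaf_angle_fractions),
        stem_xy=stem_xy,
    )


def make_physiology(fix: SpeciesFixture, theta: float = 0.7) -> SpeciesPhysiology:
    return SpeciesPhysiology(
        n_o=fix.n_o,
        pmax_slope=fix.pmax_slope,
        r_d=fix.r_d,
        quantum_yield=fix.quantum_yield,
        theta=theta,
        name=fix.name,
    )


_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "tree_height": (0.3, 3.0),
    "crown_volume": (0.005, 0.2),
    "lw_ratio": (0.8, 2.5),
    "lad_factor": (0.5, 2.0),  # lad = leaf_area/V times this
    "leaf_area_index_of_crown": (2.0, 10.0),  # lad used to draw leaf area
    "stand_height": (0.5, 3.0),
    "stand_lai": (0.0, 8.0),
    "gap_radius": (0.0, 2.5),
    "n_o": (60.0, 120.0),
    "pmax_slope": (0.05, 0.3),
    "r_d": (0.1, 1.5),
    "quantum_yield": (0.02, 0.06),
}


def random_scene(
    seed: int, ranges: dict[str, tuple[float, float]] | None = None
) -> tuple[Scene, SpeciesPhysiology]:
    """Seeded synthetic scene: a plausible tree, stand, gap and physiology.

    Draws uniformly from ``ranges`` (defaults cover the field ranges of the
    study system: seedling-to-sapling trees in shrub/grass fallow
    vegetation).  Infeasible draws (crown longer than the tree) are
    resampled; impossible ranges raise ``ValueError``.
    """
    rng = np.random.default_rng(seed)
    r = dict(_DEFAULT_RANGES)
    if ranges:
        unknown = set(ranges) - set(r)
        if unknown:
            raise ValueError(f"unknown range keys: {sorted(unknown)}")
        r.update(ranges)

    def draw(key: str) -> float:
        lo, hi = r[key]
        return float(rng.uniform(lo, hi))

    tree = None
    for _ in range(200):
        height = draw("tree_height")
        volume = draw("crown_volume")
        rho = draw("lw_ratio")
        lad_crown = draw("leaf_area_index_of_crown")
        leaf_area = lad_crown * volume
        lad = leaf_area / volume * draw("lad_factor")
        fracs = rng.dirichlet(np.ones(3))
        fracs = tuple(np.round(fracs / fracs.sum(), 6))
        try:
            tree = build_tree(
                height=height,
                crown_volume=volume,
                lw_ratio=rho,
                leaf_area=leaf_area,
                lad=lad,
                leaf_angles=LeafAngleDistribution(LEAF_ANGLE_CLASSES, fracs),
            )
            break
        except ValueError:
            continue
    if tree is None:
        raise ValueError("infeasible ranges: could not fit a crown under tree height")

    stand = VegetationStand(height=draw("stand_height"), lai=draw("stand_lai"))
    gap = Gap(radius=draw("gap_radius"))
    phys = SpeciesPhysiology(
        n_o=draw("n_o"),
        pmax_slope=draw("pmax_slope"),
        r_d=draw("r_d"),
        quantum_yield=draw("quantum_yield"),
        name=f"synthetic-{seed}",
    )
    return Scene(tree=tree, stand=stand, gap=gap), phys
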