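"""Liberation experiments: gap-radius, LAI and height sweeps, stand scenarios.

Each experiment evaluates whole-crown light capture and net photosynthesis
over a grid of scene variations and returns a tidy DataFrame.  All runs are
deterministic given the inputs: repeated calls are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import Gap, Scene, TreeGeometry, VegetationStand
from .light import (
    DEFAULT_CROWN_RESOLUTION,
    CrownQuadrature,
    SkyModel,
    build_sky,
    crown_quadrature,
)
from .photosynthesis import (
    CrownResult,
    SpeciesPhysiology,
    acclimated_relative_light,
    crown_photosynthesis,
)

__all__ = [
    "LiberationResult",
    "default_radii",
    "evaluate_crown",
    "simulate_liberation",
    "gap_radius_sweep",
    "lai_sweep",
    "height_sweep",
    "stand_scenarios",
    "first_negative_height",
]

log = logging.getLogger(__name__)

DEFAULT_FIXED_GAP_RADIUS = 0.5  # m, the field liberation treatment
DEFAULT_NORMALIZATION_RADIUS = 2.5  # m, where capture saturates for all species


def default_radii(n: int = 16, r_min: float = 0.05, r_max: float = 2.5) -> np.ndarray:
    """0 plus ``n`` log-spaced gap radii from ``r_min`` to ``r_max`` (m)."""
    return np.concatenate(([0.0], np.geomspace(r_min, r_max, n)))


def evaluate_crown(
    tree: TreeGeometry,
    physiology: SpeciesPhysiology,
    stand: VegetationStand,
    gap_radius: float,
    sky: SkyModel | None = None,
    grid: CrownQuadrature | None = None,
    resolution=DEFAULT_CROWN_RESOLUTION,
    acclimation_rel_light=None,
) -> CrownResult:
    """Run the full model for one tree/stand/gap combination."""
    if sky is None:
        sky = build_sky()
    if grid is None:
        grid = crown_quadrature(tree, resolution)
    scene = Scene(tree=tree, stand=stand, gap=Gap(gap_radius))
    log.debug(
        "evaluate_crown: gap=%.3f m, stand LAI=%.2f h=%.2f, tree h=%.2f",
        gap_radius, stand.lai, stand.height, tree.height,
    )
    return crown_photosynthesis(
        scene, physiology, sky, grid, acclimation_rel_light=acclimation_rel_light
    )


@dataclass(frozen=True)
class LiberationResult:
    """Paired control (intact canopy) and liberated (gap) crown results."""

    control: CrownResult
    liberated: CrownResult
    gap_radius: float

    @property
    def delta_phi(self) -> float:
        return self.liberated.phi - self.control.phi

    @property
    def delta_p(self) -> float:
        return self.liberated.p - self.control.p

    @property
    def delta_phi_area(self) -> float:
        return self.liberated.phi_area - self.control.phi_area

    @property
    def delta_p_area(self) -> float:
        return self.liberated.p_area - self.control.p_area

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, res, r in (
            ("control", self.control, 0.0),
            ("liberated", self.liberated, self.gap_radius),
        ):
            rows.append(
                {
                    "treatment": label,
                    "gap_radius": r,
                    "phi": res.phi,
                    "p": res.p,
                    "phi_area": res.phi_area,
                    "p_area": res.p_area,
                }
            )
        return pd.DataFrame(rows)


def simulate_liberation(
    tree: TreeGeometry,
    physiology: SpeciesPhysiology,
    stand: VegetationStand,
    gap_radius: float = DEFAULT_FIXED_GAP_RADIUS,
    sky: SkyModel | None = None,
    resolution=DEFAULT_CROWN_RESOLUTION,
) -> LiberationResult:
    """Compare an intact canopy with a liberation gap of ``gap_radius``."""
    if sky is None:
        sky = build_sky()
    grid = crown_quadrature(tree, resolution)
    acclim = acclimated_relative_light(
        Scene(tree=tree, stand=stand, gap=Gap(0.0)), sky, grid
    )
    control = evaluate_crown(
        tree, physiology, stand, 0.0, sky, grid, acclimation_rel_light=acclim
    )
    if gap_radius == 0.0:
        liberated = control
    else:
        liberated = evaluate_crown(
            tree, physiology, stand, gap_radius, sky, grid,
            acclimation_rel_light=acclim,
        )
    return LiberationResult(control=control, liberated=liberated, gap_radius=gap_radius)


def _sweep_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)


def gap_radius_sweep(
    tree: TreeGeometry,
    physiology: SpeciesPhysiology,
    stand: VegetationStand,
    radii: Sequence[float] | None = None,
    normalization_radius: float = DEFAULT_NORMALIZATION_RADIUS,
    sky: SkyModel | None = None,
    resolution=DEFAULT_CROWN_RESOLUTION,
) -> pd.DataFrame:
    """Sweep the liberation-gap radius.

    Returns one row per radius with absolute rates and percent-of-maximum
    columns normalised to the rate at ``normalization_radius``.
    """
    if radii is None:
        radii = default_radii()
    radii = list(radii)
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly increasing")
    if sky is None:
        sky = build_sky()
    grid = crown_quadrature(tree, resolution)
    acclim = acclimated_relative_light(
        Scene(tree=tree, stand=stand, gap=Gap(0.0)), sky, grid
    )

    results = {
        r: evaluate_crown(
            tree, physiology, stand, r, sky, grid, acclimation_rel_light=acclim
        )
        for r in radii
    }
    if normalization_radius not in results:
        results[normalization_radius] = evaluate_crown(
            tree, physiology, stand, normalization_radius, sky, grid,
            acclimation_rel_light=acclim,
        )
    ref = results[normalization_radius]
    rows = []
    for r in radii:
        res = results[r]
        rows.append(
            {
                "gap_radius": r,
                "phi": res.phi,
                "p": res.p,
                "phi_area": res.phi_area,
                "p_area": res.p_area,
                "phi_pct_max": 100.0 * res.phi / ref.phi,
                "p_pct_max": 100.0 * res.p / ref.p,
            }
        )
    return _sweep_frame(rows)


def lai_sweep(
    tree: TreeGeometry,
    physiology: SpeciesPhysiology,
    stand_height: float,
    lai_values: Sequence[float],
    mode: str = "control",
    gap_radius: float = DEFAULT_FIXED_GAP_RADIUS,
    sky: SkyModel | None = None,
    resolution=DEFAULT_CROWN_RESOLUTION,
) -> pd.DataFrame:
    """Sweep the LAI of the surrounding vegetation at fixed stand height.

    ``mode="control"`` keeps the canopy intact; ``mode="liberated"`` opens a
    fixed gap (default 0.5 m) at every LAI.
    """
    if mode not in ("control", "liberated"):
        raise ValueError("mode must be 'control' or 'liberated'")
    r_gap = gap_radius if mode == "liberated" else 0.0
    if sky is None:
        sky = build_sky()
    grid = crown_quadrature(tree, resolution)
    rows = []
    for lai in lai_values:
        if lai < 0:
            raise ValueError("LAI must be >= 0")
        stand = VegetationStand(height=stand_height, lai=float(lai))
        res = evaluate_crown(tree, physiology, stand, r_gap, sky, grid)
        rows.append(
            {
                "lai": float(lai),
                "mode": mode,
                "gap_radius": r_gap,
                "phi": res.phi,
                "p": res.p,
                "phi_area": res.phi_area,
                "p_area": res.p_area,
            }
        )
    return _sweep_frame(rows)


def height_sweep(
    tree: TreeGeometry,
    physiology: SpeciesPhysiology,
    lad_veg: float,
    heights: Sequence[float],
    mode: str = "control",
    gap_radius: float = DEFAULT_FIXED_GAP_RADIUS,
    sky: SkyModel | None = None,
    resolution=DEFAULT_CROWN_RESOLUTION,
) -> pd.DataFrame:
    """Sweep vegetation height at constant leaf area density.

    LAI is recomputed as ``lad_veg * height`` at every step, so taller
    vegetation also carries more leaf area.
    """
    if mode not in ("control", "liberated"):
        raise ValueError("mode must be 'control' or 'liberated'")
    if lad_veg < 0:
        raise ValueError("lad_veg must be >= 0")
    r_gap = gap_radius if mode == "liberated" else 0.0
    if sky is None:
        sky = build_sky()
    grid = crown_quadrature(tree, resolution)
    rows = []
    for h in heights:
        if h <= 0:
            raise ValueError("vegetation height must be > 0")
        stand = VegetationStand(height=float(h), lai=lad_veg * float(h))
        res = evaluate_crown(tree, physiology, stand, r_gap, sky, grid)
        rows.append(
            {
                "veg_height": float(h),
                "lai": stand.lai,
                "mode": mode,
                "gap_radius": r_gap,
                "phi": res.phi,
                "p": res.p,
                "phi_area": res.phi_area,
                "p_area": res.p_area,
            }
        )
    return _sweep_frame(rows)


def first_negative_height(sweep: pd.DataFrame) -> float:
    """First grid height at which net photosynthesis turns negative (or NaN)."""
    neg = sweep.loc[sweep["p"] < 0.0, "veg_height"]
    return float(neg.iloc[0]) if len(neg) else float("nan")


def stand_scenarios(
    species_cases: Iterable[tuple[str, TreeGeometry, SpeciesPhysiology]],
    stands: Iterable,
    radii: Sequence[float] | None = None,
    normalization_radius: float = DEFAULT_NORMALIZATION_RADIUS,
    sky: SkyModel | None = None,
    resolution=DEFAULT_CROWN_RESOLUTION,
) -> pd.DataFrame:
    """Liberation with variable gap radii across successional stands.

    ``stands`` yields objects with ``label``, ``lai`` and ``height``
    attributes.  Photosynthesis is reported both as a percentage of the
    control (gap radius 0) and of the maximum (rate at
    ``normalization_radius``).  Species cases built from the packaged mean
    parameters are a mean-tree approximation of the per-individual field
    runs.
    """
    if radii is None:
        radii = default_radii()
    radii = list(radii)
    if sky is None:
        sky = build_sky()
    rows = []
    for name, tree, phys in species_cases:
        grid = crown_quadrature(tree, resolution)
        for st in stands:
            stand = VegetationStand(height=st.height, lai=st.lai)
            acclim = acclimated_relative_light(
                Scene(tree=tree, stand=stand, gap=Gap(0.0)), sky, grid
            )
            cache = {
                r: evaluate_crown(
                    tree, phys, stand, r, sky, grid, acclimation_rel_light=acclim
                )
                for r in radii
            }
            for special in (0.0, normalization_radius):
                if special not in cache:
                    cache[special] = evaluate_crown(
                        tree, phys, stand, special, sky, grid,
                        acclimation_rel_light=acclim,
                    )
            control = cache[0.0]
            ref = cache[normalization_radius]
            for r in radii:
                res = cache[r]
                rows.append(
                    {
                        "stand": st.label,
                        "species": name,
                        "gap_radius": r,
                        "phi": res.phi,
                        "p": res.p,
                        "phi_area": res.phi_area,
                        "p_area": res.p_area,
                        "p_pct_control": 100.0 * res.p / control.p,
                        "p_pct_max": 100.0 * res.p / ref.p,
                    }
                )
    return _sweep_frame(rows)
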