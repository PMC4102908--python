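"""Shared fixtures: packaged species/stands, coarse numerics, marching oracle."""

from __future__ import annotations

import numpy as np
import pytest

import pholiage as ph

# Coarse-but-adequate resolutions for qualitative full-model tests.
COARSE_GRID = (8, 8, 8)
COARSE_SKY = (6, 8)


@pytest.fixture(scope="session")
def species_cases():
    """(name, TreeGeometry, SpeciesPhysiology) for the three packaged species."""
    return [
        (f.name, ph.make_tree(f), ph.make_physiology(f)) for f in ph.species_table2()
    ]


@pytest.fixture(scope="session")
def stand3():
    st = [s for s in ph.stands_table1() if s.label == "III"][0]
    return ph.VegetationStand(height=st.height, lai=st.lai)


@pytest.fixture(scope="session")
def sky_default():
    return ph.build_sky()


@pytest.fixture(scope="session")
def sky_coarse():
    return ph.build_sky(*COARSE_SKY)


def march_path_length(origin, direction, inside, t_max, step=1e-3) -> float:
    """Fixed-step marching estimate of the path length inside a region.

    ``inside`` maps an (N, 3) array of points to a boolean mask.  Midpoint
    sampling with a 1 mm step bounds the error by roughly one step per
    boundary crossing.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    ts = np.arange(step / 2.0, t_max, step)
    pts = origin[None, :] + ts[:, None] * direction[None, :]
    return step * int(np.count_nonzero(inside(pts)))


def inside_slab(z_top):
    return lambda p: (p[:, 2] >= 0.0) & (p[:, 2] <= z_top)


def inside_cylinder(radius, cx=0.0, cy=0.0):
    return lambda p: (p[:, 0] - cx) ** 2 + (p[:, 1] - cy) ** 2 <= radius**2


def inside_ellipsoid(tree):
    a, _, c = tree.semi_axes

    def fn(p):
        return (
            ((p[:, 0] - tree.stem_xy[0]) / a) ** 2
            + ((p[:, 1] - tree.stem_xy[1]) / a) ** 2
            + ((p[:, 2] - tree.crown_center_z) / c) ** 2
        ) <= 1.0

    return fn


def inside_vegetation(scene):
    slab = inside_slab(scene.stand.height)
    gap = inside_cylinder(
        scene.gap.radius, scene.tree.stem_xy[0], scene.tree.stem_xy[1]
    )
    crown = inside_ellipsoid(scene.tree)
    return lambda p: slab(p) & ~gap(p) & ~crown(p)


def random_upward_direction(rng, min_elevation_deg=5.0):
    beta = np.radians(rng.uniform(min_elevation_deg, 90.0))
    az = rng.uniform(0.0, 2.0 * np.pi)
    return np.array(
        [np.cos(beta) * np.cos(az), np.cos(beta) * np.sin(az), np.sin(beta)]
    )
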