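"""Scene geometry: crown reconstruction and ray–solid path lengths."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pholiage as ph
from pholiage.geometry import media_path_lengths

from conftest import (
    inside_cylinder,
    inside_ellipsoid,
    inside_slab,
    inside_vegetation,
    march_path_length,
    random_upward_direction,
)


class TestBuildTree:
    def test_unit_ellipsoid_identity(self):
        tree = ph.build_tree(height=2.0, crown_volume=math.pi / 6.0, lw_ratio=1.0,
                             leaf_area=1.0)
        assert tree.crown_width == pytest.approx(1.0, abs=1e-12)
        assert tree.crown_length == pytest.approx(1.0, abs=1e-12)
        assert tree.crown_base == pytest.approx(1.0, abs=1e-12)

    def test_microcarpus_dimensions_from_volume_and_ratio(self):
        # w = (6*0.04/(pi*1.18))^(1/3), l = 1.18 w
        tree = ph.build_tree(height=1.26, crown_volume=0.04, lw_ratio=1.18,
                             leaf_area=0.29)
        assert tree.crown_width == pytest.approx(0.40154, abs=5e-4)
        assert tree.crown_length == pytest.approx(0.47382, abs=5e-4)
        assert tree.crown_volume == pytest.approx(0.04, rel=1e-9)

    def test_lad_defaults_to_leaf_area_over_volume(self):
        tree = ph.build_tree(height=1.26, crown_volume=0.04, lw_ratio=1.18,
                             leaf_area=0.29)
        assert tree.lad == pytest.approx(0.29 / 0.04, rel=1e-12)

    def test_rejects_crown_longer_than_tree(self):
        with pytest.raises(ValueError, match="crown longer"):
            ph.build_tree(height=0.3, crown_volume=0.04, lw_ratio=2.0, leaf_area=0.1)

    def test_warns_on_inconsistent_lad(self):
        with pytest.warns(UserWarning, match="factor 2"):
            ph.build_tree(height=2.0, crown_volume=0.1, lw_ratio=1.0,
                          leaf_area=0.1, lad=10.0)


class TestLeafAngleDistribution:
    def test_spherical_preset(self):
        dist = ph.LeafAngleDistribution.spherical()
        assert dist.is_spherical

    @pytest.mark.parametrize(
        "angles,fracs",
        [((15.0, 45.0), (0.6, 0.6)),      # sums to 1.2
         ((100.0,), (1.0,)),               # angle out of range
         ((15.0,), (1.5,))],               # fraction out of range
    )
    def test_rejects_invalid(self, angles, fracs):
        with pytest.raises(ValueError):
            ph.LeafAngleDistribution(angles, fracs)

    def test_accepts_printed_rounding(self):
        # printed class fractions may sum to 1.01
        dist = ph.LeafAngleDistribution((15.0, 45.0, 75.0), (0.37, 0.40, 0.24))
        assert sum(dist.fractions) == pytest.approx(1.01)


class TestScalarPaths:
    def test_slab_vertical(self):
        ray = ph.Ray((0, 0, 0), (0, 0, 1))
        assert ph.ray_slab_path(ray, 1.4) == pytest.approx(1.4)

    def test_slab_oblique_is_h_over_sin_beta(self):
        ray = ph.Ray.from_angles((0, 0, 0), elevation_deg=30.0)
        assert ph.ray_slab_path(ray, 1.4) == pytest.approx(2.8)

    def test_slab_origin_above(self):
        ray = ph.Ray((0, 0, 2.0), (0, 0, 1))
        assert ph.ray_slab_path(ray, 1.4) == 0.0

    def test_ellipsoid_center_to_surface(self):
        tree = ph.build_tree(height=3.0, crown_volume=math.pi / 6 * 8, lw_ratio=1.0,
                             leaf_area=1.0)  # unit sphere radius 1 (l=w=2)
        ray = ph.Ray((0, 0, tree.crown_center_z), (0, 0, 1))
        assert ph.ray_ellipsoid_chord(ray, tree) == pytest.approx(1.0, abs=1e-12)

    def test_ellipsoid_outward_from_surface(self):
        tree = ph.build_tree(height=3.0, crown_volume=math.pi / 6 * 8, lw_ratio=1.0,
                             leaf_area=1.0)
        ray = ph.Ray((0, 0, tree.crown_center_z + 1.0), (0, 0, 1))
        assert ph.ray_ellipsoid_chord(ray, tree) == pytest.approx(0.0, abs=1e-12)

    def test_cylinder_zero_radius(self):
        ray = ph.Ray.from_angles((0.1, 0.0, 0.0), 45.0, 10.0)
        assert ph.ray_cylinder_path(ray, ph.Gap(0.0), 1.4) == 0.0

    def test_cylinder_axis_vertical_ray(self):
        ray = ph.Ray((0, 0, 0), (0, 0, 1))
        assert ph.ray_cylinder_path(ray, ph.Gap(0.5), 1.4) == pytest.approx(1.4)

    def test_vegetation_path_zero_above_canopy(self, stand3):
        tree = ph.make_tree(ph.species_table2()[0])
        scene = ph.Scene(tree=tree, stand=stand3, gap=ph.Gap(0.5))
        d = random_upward_direction(np.random.default_rng(0))
        assert ph.vegetation_path_length((0.3, 0.2, stand3.height), d, scene) == 0.0

    def test_vegetation_path_zero_inside_gap_column(self, stand3):
        tree = ph.make_tree(ph.species_table2()[1])
        scene = ph.Scene(tree=tree, stand=stand3, gap=ph.Gap(0.5))
        # vertical ray up the stem axis: gap column plus crown cover it all
        assert ph.vegetation_path_length((0, 0, 0), (0, 0, 1), scene) == 0.0


@pytest.fixture(scope="module")
def scene(stand3):
    tree = ph.make_tree(ph.species_table2()[0])
    return ph.Scene(tree=tree, stand=stand3, gap=ph.Gap(0.4))


class TestMarchingOracle:
    """Analytic chords vs a 1 mm fixed-step marching estimate."""

    def _random_ray(self, rng):
        origin = np.array([rng.uniform(-1.0, 1.0), rng.uniform(-1.0, 1.0),
                           rng.uniform(0.0, 1.5)])
        return origin, random_upward_direction(rng, min_elevation_deg=10.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_ellipsoid_chord(self, scene, seed):
        rng = np.random.default_rng(100 + seed)
        origin, d = self._random_ray(rng)
        got = ph.ray_ellipsoid_chord(ph.Ray(tuple(origin), tuple(d)), scene.tree)
        want = march_path_length(origin, d, inside_ellipsoid(scene.tree), t_max=6.0)
        assert got == pytest.approx(want, abs=2e-3)

    @pytest.mark.parametrize("seed", range(12))
    def test_cylinder_path(self, scene, seed):
        rng = np.random.default_rng(200 + seed)
        origin, d = self._random_ray(rng)
        got = ph.ray_cylinder_path(
            ph.Ray(tuple(origin), tuple(d)), scene.gap, scene.stand.height
        )
        inside = lambda p: inside_cylinder(scene.gap.radius)(p) & inside_slab(
            scene.stand.height
        )(p)
        want = march_path_length(origin, d, inside, t_max=12.0)
        assert got == pytest.approx(want, abs=2e-3)

    @pytest.mark.parametrize("seed", range(12))
    def test_vegetation_path(self, scene, seed):
        rng = np.random.default_rng(300 + seed)
        origin, d = self._random_ray(rng)
        got = ph.vegetation_path_length(origin, d, scene)
        want = march_path_length(origin, d, inside_vegetation(scene), t_max=12.0)
        assert got == pytest.approx(want, abs=5e-3)


class TestMediaPartition:
    def test_paths_bounded_by_slab(self, stand3, species_cases):
        rng = np.random.default_rng(7)
        _, tree, _ = species_cases[0]
        scene = ph.Scene(tree=tree, stand=stand3, gap=ph.Gap(0.6))
        for _ in range(50):
            origin = np.array([rng.uniform(-2, 2), rng.uniform(-2, 2),
                               rng.uniform(0, 1.3)])
            d = random_upward_direction(rng)
            s_veg, _ = media_path_lengths(origin[None, :], d, scene)
            slab = ph.ray_slab_path(ph.Ray(tuple(origin), tuple(d)), stand3.height)
            assert 0.0 <= s_veg[0] <= slab + 1e-12

    def test_partition_without_gap(self, stand3, species_cases):
        """veg + crown = slab when the crown is inside the slab and no gap."""
        _, tree, _ = species_cases[2]  # crown fully below stand III top
        assert tree.height <= stand3.height
        scene = ph.Scene(tree=tree, stand=stand3, gap=ph.Gap(0.0))
        rng = np.random.default_rng(11)
        for _ in range(50):
            origin = np.array([rng.uniform(-1, 1), rng.uniform(-1, 1),
                               rng.uniform(0, 1.3)])
            d = random_upward_direction(rng)
            s_veg, s_crown = media_path_lengths(origin[None, :], d, scene)
            slab = ph.ray_slab_path(ph.Ray(tuple(origin), tuple(d)), stand3.height)
            assert s_veg[0] + s_crown[0] == pytest.approx(slab, abs=1e-10)

    def test_partition_crown_above_slab(self):
        """veg + gap = slab when the crown sits entirely above the vegetation."""
        tree = ph.build_tree(height=2.0, crown_volume=0.05, lw_ratio=1.0,
                             leaf_area=0.2)
        stand = ph.VegetationStand(height=1.0, lai=3.0)
        assert tree.crown_base > stand.height
        scene = ph.Scene(tree=tree, stand=stand, gap=ph.Gap(0.5))
        rng = np.random.default_rng(13)
        for _ in range(50):
            origin = np.array([rng.uniform(-1, 1), rng.uniform(-1, 1),
                               rng.uniform(0, 0.9)])
            d = random_upward_direction(rng)
            ray = ph.Ray(tuple(origin), tuple(d))
            s_veg, _ = media_path_lengths(origin[None, :], d, scene)
            gap_path = ph.ray_cylinder_path(ray, scene.gap, stand.height)
            slab = ph.ray_slab_path(ray, stand.height)
            assert s_veg[0] + gap_path == pytest.approx(slab, abs=1e-10)

    def test_zero_gap_is_bit_exact_no_gap(self, stand3, species_cases):
        """radius 0 reproduces the intact canopy with no tolerance at all."""
        _, tree, _ = species_cases[0]
        with_gap = ph.Scene(tree=tree, stand=stand3, gap=ph.Gap(0.0))
        rng = np.random.default_rng(17)
        pts = np.column_stack([
            rng.uniform(-1, 1, 40), rng.uniform(-1, 1, 40), rng.uniform(0, 1.3, 40)
        ])
        d = random_upward_direction(rng)
        s_veg, s_crown = media_path_lengths(pts, d, with_gap)
        # intact reference: slab minus crown only, via the same interval code
        ref_scene = ph.Scene(tree=tree, stand=stand3, gap=ph.Gap(0.0))
        s_veg_ref, s_crown_ref = media_path_lengths(pts, d, ref_scene)
        assert np.array_equal(s_veg, s_veg_ref)
        assert np.array_equal(s_crown, s_crown_ref)
        # and the gap makes no contribution anywhere
        for i in range(len(pts)):
            ray = ph.Ray(tuple(pts[i]), tuple(d))
            assert ph.ray_cylinder_path(ray, ph.Gap(0.0), stand3.height) == 0.0


class TestSymmetries:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        dx=st.floats(-5, 5), dy=st.floats(-5, 5),
        rot=st.floats(0, 2 * math.pi),
        oz=st.floats(0.0, 1.3), beta=st.floats(0.1, math.pi / 2),
    )
    def test_translation_and_rotation_invariance(self, dx, dy, rot, oz, beta):
        stand = ph.VegetationStand(height=1.4, lai=3.73)
        gap = ph.Gap(0.5)
        tree0 = ph.build_tree(1.26, 0.04, 1.18, 0.29)
        tree1 = ph.build_tree(1.26, 0.04, 1.18, 0.29, stem_xy=(dx, dy))
        origin = np.array([0.4, -0.2, oz])
        d = np.array([math.cos(beta), 0.0, math.sin(beta)])
        base = ph.vegetation_path_length(origin, d, ph.Scene(tree0, stand, gap))
        # translate scene and ray together
        shifted = ph.vegetation_path_length(
            origin + np.array([dx, dy, 0.0]), d, ph.Scene(tree1, stand, gap)
        )
        assert shifted == pytest.approx(base, abs=1e-9)
        # rotate ray about the (vertical) stem axis of the unshifted scene
        c, s = math.cos(rot), math.sin(rot)
        rot_origin = np.array(
            [c * origin[0] - s * origin[1], s * origin[0] + c * origin[1], origin[2]]
        )
        rot_d = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1], d[2]])
        rotated = ph.vegetation_path_length(rot_origin, rot_d, ph.Scene(tree0, stand, gap))
        assert rotated == pytest.approx(base, abs=1e-9)
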