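"""Lesion overlap metrics (DSC, HD95) and lesion characteristics."""

import numpy as np
import pytest
import trimesh

from navphantom import (
    LesionModel,
    RigidFit,
    dsc,
    hd95,
    l2_norm,
    lesion_depth,
    percentile_max,
    surface_points,
    transform_lesion,
)


def cube_mask(n=10, pad=6, offset=(0, 0, 0)):
    """An n^3 cube of foreground centered in a padded grid."""
    shape = (n + 2 * pad,) * 3
    mask = np.zeros(shape, dtype=bool)
    o = np.array(offset) + pad
    mask[o[0]:o[0] + n, o[1]:o[1] + n, o[2]:o[2] + n] = True
    return LesionModel(mask)


def translation_fit(t):
    return RigidFit(np.eye(3), np.asarray(t, float), np.zeros((1, 3)), (1,))


class TestLesionModel:
    def test_volume_is_voxel_count_times_voxel_volume(self):
        m = cube_mask(n=10)
        assert m.volume_cm3 == pytest.approx(1000 * 1.0 / 1000.0)
        m2 = LesionModel(m.mask, spacing=(0.5, 0.5, 2.0))
        assert m2.volume_cm3 == pytest.approx(1000 * 0.5 * 0.5 * 2.0 / 1000.0)

    def test_centroid_in_world_coordinates(self):
        m = LesionModel(
            cube_mask(n=10).mask, spacing=(2.0, 1.0, 1.0), origin=(5.0, -3.0, 0.0)
        )
        idx_centroid = np.argwhere(m.mask).mean(axis=0)
        np.testing.assert_allclose(
            m.centroid, idx_centroid * [2.0, 1.0, 1.0] + [5.0, -3.0, 0.0]
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            LesionModel(np.zeros((4, 4, 4), dtype=bool))


class TestTransformLesion:
    def test_identity_preserves_mask_voxel_for_voxel(self):
        gt = cube_mask()
        tm = transform_lesion(gt, RigidFit.identity())
        np.testing.assert_array_equal(tm.mask, gt.mask)

    def test_one_voxel_translation_is_index_shift(self):
        gt = cube_mask()
        tm = transform_lesion(gt, translation_fit([1.0, 0.0, 0.0]))
        np.testing.assert_array_equal(tm.mask, np.roll(gt.mask, 1, axis=0))

    def test_quarter_turn_preserves_symmetric_cube(self):
        gt = cube_mask()
        centroid = gt.centroid
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        # rotation about the cube centroid, expressed about the origin
        t = centroid - rot @ centroid
        tm = transform_lesion(gt, RigidFit(rot, t, np.zeros((1, 3)), (1,)))
        np.testing.assert_array_equal(tm.mask, gt.mask)


class TestDSC:
    def test_perfect_and_disjoint(self):
        gt = cube_mask()
        assert dsc(gt, gt) == 1.0
        shifted = transform_lesion(gt, translation_fit([0, 0, 11.0]))
        assert dsc(gt, shifted) == 0.0

    def test_half_overlapping_cubes(self):
        # two 10^3 cubes overlapping in a 5x10x10 block: 2*500/2000 = 0.5
        gt = cube_mask()
        tm = transform_lesion(gt, translation_fit([5.0, 0.0, 0.0]))
        assert dsc(gt, tm) == pytest.approx(0.5)

    def test_symmetric(self):
        a = cube_mask()
        b = transform_lesion(a, translation_fit([3.0, 2.0, 0.0]))
        assert dsc(a, b) == dsc(b, a)

    def test_grid_mismatch_rejected(self):
        a = cube_mask()
        b = LesionModel(a.mask, origin=(1.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="grid"):
            dsc(a, b)


class TestHD95:
    def test_zero_for_identical_masks(self):
        gt = cube_mask()
        assert hd95(gt, gt) == 0.0

    def test_percentile_rule_on_constructed_multiset(self):
        d = np.array([1.0] * 95 + [10.0] * 5)
        assert percentile_max(d) == pytest.approx(1.0)
        # a different split: 90 small, 10 large -> the 95th sorted value is large
        d2 = np.array([1.0] * 90 + [10.0] * 10)
        assert percentile_max(d2) == pytest.approx(10.0)

    def test_translated_slab_within_one_voxel(self):
        # large flat slab moved 2 mm: almost all GT surface voxels sit on the
        # broad faces, whose nearest TM face is 2 mm away
        mask = np.zeros((40, 40, 12), dtype=bool)
        mask[2:38, 2:38, 4:8] = True
        gt = LesionModel(mask)
        tm = transform_lesion(gt, translation_fit([0.0, 0.0, 2.0]))
        d = hd95(gt, tm)
        assert d == pytest.approx(2.0, abs=1.0)
        # brute-force nearest-neighbour cross-check
        g, t = surface_points(gt), surface_points(tm)
        dists = np.sort(
            np.min(np.linalg.norm(g[:, None] - t[None], axis=-1), axis=1)
        )
        k = int(np.ceil(0.95 * len(dists)))
        assert d == pytest.approx(dists[k - 1])

    def test_symmetric_variant_takes_max_direction(self):
        # grow GT into TM: directed GT->TM distance is 0 (GT surface inside
        # TM's surface set neighbourhood differs) — use asymmetric shapes
        small = cube_mask(n=6, pad=8)
        big = cube_mask(n=14, pad=4)
        directed = hd95(small, big)
        symmetric = hd95(small, big, symmetric=True)
        assert symmetric >= directed

    def test_surface_is_boundary_voxels_only(self):
        gt = cube_mask(n=10)
        pts = surface_points(gt)
        assert len(pts) == 10**3 - 8**3  # cube shell under 6-connectivity


class TestDepthAndL2:
    def make_sphere(self, radius=80.0, subdivisions=4):
        return trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)

    def test_depth_at_sphere_center(self):
        skin = self.make_sphere()
        assert lesion_depth([0.0, 0.0, 0.0], skin) == pytest.approx(8.0, abs=0.02)

    def test_depth_off_center(self):
        skin = self.make_sphere()
        assert lesion_depth([30.0, 0.0, 0.0], skin) == pytest.approx(5.0, abs=0.02)

    def test_depth_zero_on_surface(self):
        skin = self.make_sphere(subdivisions=2)
        vertex = skin.vertices[0]
        assert lesion_depth(vertex, skin) == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_mesh_rejected(self):
        flat = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 1, 1], [2, 2, 2]], faces=[[0, 1, 2]],
            process=False,
        )
        with pytest.raises(ValueError, match="degenerate"):
            lesion_depth([0.0, 0.0, 0.0], flat)

    @pytest.mark.parametrize(
        "point,expected",
        [((0, 0, 0), 0.0), ((30, 40, 0), 5.0), ((10, 10, 10), np.sqrt(300) / 10)],
    )
    def test_l2_norm(self, point, expected):
        assert l2_norm(point) == pytest.approx(expected)


def test_dsc_increases_with_volume_at_fixed_misregistration():
    from scipy.stats import spearmanr

    from navphantom import dsc_volume_simulation

    df = dsc_volume_simulation(n_lesions=21, translation_mm=3.0, seed=0)
    rho, _ = spearmanr(df["volume_cm3"], df["dsc"])
    assert rho > 0
    # and monotone in the family: larger lesion never loses DSC by much
    assert df["dsc"].iloc[-1] > df["dsc"].iloc[0]


class TestPercentileMaxProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(st.floats(0.0, 1e4), min_size=1, max_size=200),
        st.floats(0.05, 1.0),
    )
    @settings(derandomize=True, max_examples=60)
    def test_result_is_an_order_statistic(self, distances, fraction):
        d = np.asarray(distances)
        result = percentile_max(d, fraction)
        assert result in d
        assert d.min() <= result <= d.max()
        # the full multiset reduces to its maximum
        assert percentile_max(d, 1.0) == d.max()
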