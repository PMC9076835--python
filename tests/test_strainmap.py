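import numpy as np
import pytest
from shapely.geometry import Polygon, box

from pappus.strainmap import (LandmarkSet, area_change, assign_regions,
                              circularity, principal_strain,
                              regional_mean_area_change,
                              relative_displacement, run_pipeline,
                              smooth_area_change, triangulate_dry)


def make_lm(dry, wet=None, outline=None, regions=None, ref=0):
    dry = np.asarray(dry, dtype=float)
    wet = dry.copy() if wet is None else np.asarray(wet, dtype=float)
    if outline is None:
        lo = dry.min(axis=0) - 1
        hi = dry.max(axis=0) + 1
        outline = box(lo[0], lo[1], hi[0], hi[1])
    return LandmarkSet(ids=np.arange(len(dry)), dry=dry, wet=wet,
                       reference_id=ref, outline_dry=outline,
                       regions=regions or {})


@pytest.fixture
def square_lm():
    dry = [(0, 0), (1, 0), (1, 1), (0, 1)]
    return make_lm(dry, outline=box(0, 0, 1, 1))


class TestRelativeDisplacement:
    def test_rigid_translation_cancels(self):
        dry = np.random.default_rng(0).uniform(0, 10, (20, 2))
        lm = make_lm(dry, dry + [3.0, -2.0])
        np.testing.assert_allclose(relative_displacement(lm), 0, atol=1e-12)

    def test_similarity_map_oracle(self):
        """wet = 1.4 x dry about the reference point."""
        dry = np.random.default_rng(1).uniform(0, 10, (15, 2))
        ref_pt = dry[4]
        wet = ref_pt + 1.4 * (dry - ref_pt)
        lm = make_lm(dry, wet, ref=4)
        expected = 0.4 * (dry - ref_pt)
        np.testing.assert_allclose(relative_displacement(lm), expected,
                                   atol=1e-12)

    def test_reference_row_is_zero(self):
        dry = np.random.default_rng(2).uniform(0, 5, (8, 2))
        wet = dry * 1.1 + 0.3
        lm = make_lm(dry, wet, ref=3)
        np.testing.assert_allclose(relative_displacement(lm)[3], 0, atol=1e-12)

    def test_unpaired_input_rejected(self):
        with pytest.raises(ValueError):
            LandmarkSet(ids=np.arange(3), dry=np.zeros((3, 2)),
                        wet=np.zeros((2, 2)), reference_id=0,
                        outline_dry=box(0, 0, 1, 1))


class TestTriangulation:
    def test_unit_square_gives_two_retained_triangles(self, square_lm):
        tmap = triangulate_dry(square_lm)
        assert len(tmap.triangles) == 2
        assert tmap.valid.all()

    def test_outline_clipping_excludes_outside_triangles(self):
        dry = [(0, 0), (1, 0), (1, 1), (0, 1)]
        lm = make_lm(dry, outline=Polygon([(0, 0), (1, 0), (1, 0.5), (0, 0.5)]))
        tmap = triangulate_dry(lm)
        assert (~tmap.valid).any()
        assert all(r == "outside-outline" for r in tmap.reason[~tmap.valid])

    def test_euler_relation_on_convex_cloud(self):
        """n points, h hull points, hull outline: 2n - h - 2 triangles."""
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 10, (40, 2))
        from scipy.spatial import ConvexHull
        hull = ConvexHull(pts)
        outline = Polygon(pts[hull.vertices])
        lm = make_lm(pts, outline=outline)
        tmap = triangulate_dry(lm)
        n, h = len(pts), len(hull.vertices)
        assert len(tmap.triangles) == 2 * n - h - 2
        assert tmap.valid.all()

    def test_collinear_landmarks_rejected(self):
        with pytest.raises(ValueError):
            triangulate_dry(make_lm([(0, 0), (1, 1), (2, 2), (3, 3)]))


class TestAreaChange:
    def test_global_affine_ratio_is_det_f(self):
        rng = np.random.default_rng(4)
        dry = rng.uniform(0, 10, (30, 2))
        F = np.array([[1.2, 0.3], [0.1, 1.3]])  # det = 1.53
        lm = make_lm(dry, dry @ F.T)
        tmap = area_change(triangulate_dry(lm), lm)
        ratios = tmap.ratio[tmap.valid]
        np.testing.assert_allclose(ratios, np.linalg.det(F), rtol=1e-9)

    def test_identity_gives_unit_ratios(self, square_lm):
        tmap = area_change(triangulate_dry(square_lm), square_lm)
        np.testing.assert_allclose(tmap.ratio[tmap.valid], 1.0, atol=1e-12)

    def test_inverted_triangle_is_flagged_and_neighbours_kept(self):
        dry = np.array([(0, 0), (2, 0), (4, 0), (1, 2), (3, 2), (2, 4.0)])
        wet = dry.copy()
        wet[5] = (2.0, -1.0)  # flips triangles containing vertex 5
        lm = make_lm(dry, wet)
        tmap = area_change(triangulate_dry(lm), lm)
        bad = ~tmap.valid
        assert bad.any()
        assert set(tmap.reason[bad]) == {"wet-overlap"}
        has5 = np.array([5 in t for t in tmap.triangles])
        assert tmap.valid[~has5 & ~bad].all()


class TestSmoothing:
    def test_constant_field_is_fixed_point(self):
        rng = np.random.default_rng(5)
        dry = rng.uniform(0, 10, (25, 2))
        lm = make_lm(dry, dry * 1.5)
        tmap = smooth_area_change(area_change(triangulate_dry(lm), lm))
        np.testing.assert_allclose(tmap.smoothed[tmap.valid],
                                   tmap.ratio[tmap.valid], rtol=1e-12)

    def test_isolated_triangle_keeps_raw_value(self):
        lm = make_lm([(0, 0), (1, 0), (0.5, 1)])
        lm.wet[:] = lm.dry * 2
        tmap = smooth_area_change(area_change(triangulate_dry(lm), lm))
        assert tmap.smoothed[0] == pytest.approx(tmap.ratio[0])

    def test_two_triangle_strip_hand_computed(self, square_lm):
        """Square split in two: each smoothed value is the pair mean."""
        lm = square_lm
        lm.wet[:] = lm.dry
        tmap = area_change(triangulate_dry(lm), lm)
        tmap.ratio = np.array([1.0, 3.0])
        tmap = smooth_area_change(tmap)
        np.testing.assert_allclose(tmap.smoothed, [2.0, 2.0])


class TestPrincipalStrain:
    def _affine_lm(self, F):
        rng = np.random.default_rng(6)
        dry = rng.uniform(0, 10, (12, 2))
        return make_lm(dry, dry @ np.asarray(F).T)

    def test_pure_diagonal_stretch(self):
        lm = self._affine_lm(np.diag([1.5, 1.0]))
        tmap = principal_strain(area_change(triangulate_dry(lm), lm), lm)
        ok = tmap.valid
        np.testing.assert_allclose(tmap.stretches[ok, 0], 1.5, rtol=1e-9)
        np.testing.assert_allclose(tmap.stretches[ok, 1], 1.0, rtol=1e-9)
        # major axis along x
        major = tmap.directions[ok, 0]
        np.testing.assert_allclose(np.abs(major[:, 0]), 1.0, atol=1e-9)

    def test_rotation_composed_with_stretch_svd_oracle(self):
        ang = np.radians(30)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        F = R @ np.diag([2.0, 1.0])
        lm = self._affine_lm(F)
        tmap = principal_strain(area_change(triangulate_dry(lm), lm), lm)
        ok = tmap.valid
        np.testing.assert_allclose(tmap.stretches[ok, 0], 2.0, rtol=1e-9)
        np.testing.assert_allclose(tmap.stretches[ok, 1], 1.0, rtol=1e-9)
        # right singular vectors live in the dry frame: still the x axis
        major = tmap.directions[ok, 0]
        np.testing.assert_allclose(np.abs(major[:, 0]), 1.0, atol=1e-9)

    def test_isotropic_scaling_consistent_with_area_ratio(self):
        lm = self._affine_lm(1.2 * np.eye(2))
        tmap = principal_strain(area_change(triangulate_dry(lm), lm), lm)
        ok = tmap.valid
        np.testing.assert_allclose(tmap.stretches[ok], 1.2, rtol=1e-9)
        prod = tmap.stretches[ok, 0] * tmap.stretches[ok, 1]
        assert np.abs(prod - tmap.ratio[ok]).max() < 1e-9


class TestRegionAssignment:
    def test_containment_threshold_and_default(self):
        dry = np.array([(0, 0), (4, 0), (4, 4), (0, 4.0)])
        lm = make_lm(dry, regions={
            "vasculature": box(-1, -1, 5, 5),       # covers everything
        })
        tmap = assign_regions(area_change(triangulate_dry(lm), lm), lm)
        assert set(tmap.region) == {"vasculature"}

    def test_39_percent_overlap_goes_to_cortex(self):
        # right triangle (0,0)-(1,0)-(0,1); region strip covers 39% of it
        dry = np.array([(0, 0), (1, 0), (0, 1.0)])
        lm = make_lm(dry, regions={"podium": box(0, 0, 1, 0.2180)})
        tmap = assign_regions(area_change(triangulate_dry(lm), lm), lm)
        tri = Polygon(dry)
        frac = tri.intersection(lm.regions["podium"]).area / tri.area
        assert frac < 0.40
        assert tmap.region[0] == "cortex"

    def test_41_percent_overlap_assigned(self):
        dry = np.array([(0, 0), (1, 0), (0, 1.0)])
        lm = make_lm(dry, regions={"podium": box(0, 0, 1, 0.2325)})
        tri = Polygon(dry)
        frac = tri.intersection(lm.regions["podium"]).area / tri.area
        assert frac > 0.40
        tmap = assign_regions(area_change(triangulate_dry(lm), lm), lm)
        assert tmap.region[0] == "podium"

    def test_no_overlap_defaults_to_cortex(self):
        dry = np.array([(0, 0), (1, 0), (0, 1.0)])
        lm = make_lm(dry, regions={"side": box(10, 10, 11, 11)})
        tmap = assign_regions(area_change(triangulate_dry(lm), lm), lm)
        assert tmap.region[0] == "cortex"


class TestCircularity:
    def test_unit_square(self):
        assert circularity(Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])) == \
            pytest.approx(np.pi / 4)

    def test_polygonal_circle_approaches_one(self):
        ang = np.linspace(0, 2 * np.pi, 361)[:-1]
        poly = Polygon(np.column_stack([np.cos(ang), np.sin(ang)]))
        assert circularity(poly) > 0.9999

    def test_elongated_rectangle(self):
        poly = Polygon([(0, 0), (10, 0), (10, 1), (0, 1)])
        assert circularity(poly) == pytest.approx(4 * np.pi * 10 / 22 ** 2)

    def test_self_intersecting_rejected(self):
        with pytest.raises(ValueError):
            circularity(Polygon([(0, 0), (1, 1), (1, 0), (0, 1)]))


class TestRegionalMeans:
    def test_uniform_ratio_means(self):
        rng = np.random.default_rng(7)
        dry = rng.uniform(0, 10, (30, 2))
        lm = make_lm(dry, dry * np.sqrt(1.5),
                     regions={"vasculature": box(0, 0, 5, 10)})
        tmap, means = run_pipeline(lm)
        for value in means.values():
            assert value == pytest.approx(1.5, rel=1e-9)

    def test_single_region_toy_mean(self, square_lm):
        lm = square_lm
        tmap = area_change(triangulate_dry(lm), lm)
        tmap.ratio = np.array([1.0, 3.0])
        tmap = smooth_area_change(tmap)
        tmap = assign_regions(tmap, lm)
        means = regional_mean_area_change(tmap)
        assert means["cortex"] == pytest.approx(2.0)

    def test_missing_region_is_nan_not_zero(self, square_lm):
        tmap, means = run_pipeline(square_lm)
        assert "podium" not in means  # absent region simply not reported


class TestRigidMotionInvariance:
    def test_outputs_invariant_under_common_rigid_motion(self):
        from pappus.synth import DeformationSpec, generate_landmarks
        lm, _ = generate_landmarks(DeformationSpec(seed=11, n_landmarks=150))
        _, means_a = run_pipeline(lm)
        ang = np.radians(17.0)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        t = np.array([5.0, -3.0])
        lm2 = LandmarkSet(ids=lm.ids, dry=lm.dry @ R.T + t,
                          wet=lm.wet @ R.T + t,
                          reference_id=lm.reference_id,
                          outline_dry=Polygon(
                              np.asarray(lm.outline_dry.exterior.coords) @ R.T + t),
                          regions={k: Polygon(
                              np.asarray(v.exterior.coords) @ R.T + t)
                              for k, v in lm.regions.items()})
        _, means_b = run_pipeline(lm2)
        for k in means_a:
            assert means_a[k] == pytest.approx(means_b[k], rel=1e-9)
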