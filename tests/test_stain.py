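"""Tests for the radial DAB stain-quantification workflow."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import ndimage

from fixtof import simulate, stain
from fixtof.errors import (
    ConfigError,
    InvalidArgumentError,
    NoAnalyzableTissueError,
    NoTissueError,
)
from fixtof.simulate import HDAB_VECTORS, SyntheticIhcSpec, simulate_ihc_image
from fixtof.stain import (
    QuantConfig,
    StainImage,
    ZoneProfile,
    compare_groups,
    edge_distance_map,
    exclude_nonstaining,
    penetration_depth,
    proper_staining_fraction,
    quantify_image,
    radial_zone_labels,
    segment_tissue,
    unmix,
    zone_profile,
)


@pytest.fixture(scope="module")
def disk_image():
    spec = SyntheticIhcSpec(tissue_radius=1.5, pixel_size=0.01, seed=4)
    rgb, truth = simulate_ihc_image(spec)
    return StainImage(rgb, pixel_size=spec.pixel_size), truth, spec


@pytest.fixture(scope="module")
def holey_image():
    spec = SyntheticIhcSpec(tissue_radius=1.5, pixel_size=0.01, seed=8,
                            hole_spec=(2, 0.08))
    rgb, truth = simulate_ihc_image(spec)
    return StainImage(rgb, pixel_size=spec.pixel_size), truth, spec


class TestSegmentation:
    def test_disk_iou(self, disk_image):
        img, truth, _ = disk_image
        mask = segment_tissue(img)
        iou = (mask & truth["tissue_mask"]).sum() / (mask | truth["tissue_mask"]).sum()
        assert iou >= 0.99

    def test_uniform_white_raises(self):
        img = StainImage(np.full((64, 64, 3), 255, np.uint8), 0.01)
        with pytest.raises(NoTissueError):
            segment_tissue(img)

    def test_brightness_scaling_invariance(self, disk_image):
        img, _, _ = disk_image
        dimmed = StainImage(
            np.clip(img.rgb.astype(float) * 0.9, 0, 255).astype(np.uint8),
            img.pixel_size,
        )
        m1, m2 = segment_tissue(img), segment_tissue(dimmed)
        iou = (m1 & m2).sum() / (m1 | m2).sum()
        assert iou >= 0.99


class TestExcludeNonstaining:
    def test_holes_removed(self, holey_image):
        img, truth, _ = holey_image
        refined = exclude_nonstaining(img, segment_tissue(img))
        excluded = truth["tissue_mask"] & ~refined
        hole_area = truth["hole_mask"].sum()
        assert abs(excluded.sum() - hole_area) <= 0.05 * hole_area

    def test_hole_free_mask_unchanged(self, disk_image):
        img, _, _ = disk_image
        mask = segment_tissue(img)
        np.testing.assert_array_equal(exclude_nonstaining(img, mask), mask)

    def test_all_white_interior_raises(self):
        rgb = np.full((64, 64, 3), 255, np.uint8)
        img = StainImage(rgb, 0.01)
        mask = np.zeros((64, 64), bool)
        mask[16:48, 16:48] = True  # mask says tissue, image is blank
        with pytest.raises(NoAnalyzableTissueError):
            exclude_nonstaining(img, mask)


class TestUnmix:
    def test_round_trip_pre_quantization(self):
        rng = np.random.default_rng(2)
        conc = rng.uniform(0, 0.8, (16, 16, 2))
        od = conc @ HDAB_VECTORS.T
        rgb = 255.0 * 10 ** (-od)  # float image: no quantization
        h, d, clip = unmix(StainImage(rgb, 0.01))
        np.testing.assert_allclose(h, conc[..., 0], atol=1e-6)
        np.testing.assert_allclose(d, conc[..., 1], atol=1e-6)
        assert clip == pytest.approx(0.0, abs=0.02)

    def test_white_pixel_is_zero(self):
        rgb = np.full((2, 2, 3), 255, np.uint8)
        h, d, _ = unmix(StainImage(rgb, 0.01))
        assert np.all(h == 0) and np.all(d == 0)

    def test_quantized_error_within_derived_bound(self):
        """8-bit rounding error propagates through the pseudo-inverse; the
        per-pixel bound |pinv| @ (0.5 / (I ln 10)) must hold."""
        rng = np.random.default_rng(3)
        conc = rng.uniform(0, 0.5, (100, 1, 2))
        od = conc @ HDAB_VECTORS.T
        rgb = np.clip(np.round(255.0 * 10 ** (-od)), 1, 255)
        h, d, _ = unmix(StainImage(rgb, 0.01))
        err = np.stack([h - conc[..., 0], d - conc[..., 1]], axis=-1)
        pinv = np.linalg.pinv(HDAB_VECTORS)
        bound = (0.5 / (rgb * np.log(10))) @ np.abs(pinv).T
        # clipping negatives can only shrink the error toward the truth
        assert np.all(np.abs(err) <= bound + 1e-9)

    def test_collinear_vectors_rejected(self):
        v = np.tile([[0.5], [0.6], [0.6]], (1, 2))
        with pytest.raises(ConfigError):
            unmix(StainImage(np.zeros((2, 2, 3), np.uint8), 0.01), v)


class TestEdgeDistance:
    def test_small_block_geometry(self):
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        d = edge_distance_map(mask, 0.1)
        assert d[2, 2] == pytest.approx(0.2)
        assert d[1, 1] == pytest.approx(0.1)
        assert np.isnan(d[0, 0])

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            mask = ndimage.binary_dilation(rng.random((32, 32)) > 0.8)
            mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
            if not mask.any():
                continue
            d = edge_distance_map(mask, 1.0)
            bg = np.argwhere(~mask)
            for y, x in np.argwhere(mask):
                brute = np.sqrt(((bg - (y, x)) ** 2).sum(axis=1)).min()
                assert d[y, x] == pytest.approx(brute, abs=1e-9)

    def test_disk_max_distance(self):
        yy, xx = np.mgrid[0:101, 0:101]
        mask = np.hypot(yy - 50, xx - 50) <= 40
        d = edge_distance_map(mask, 0.01)
        assert abs(np.nanmax(d) - 0.40) <= 0.01

    def test_empty_mask(self):
        with pytest.raises(InvalidArgumentError):
            edge_distance_map(np.zeros((4, 4), bool), 0.01)


class TestZoning:
    def test_floor_arithmetic(self):
        d = np.array([[0.0, 0.1, 0.34, 0.67]])
        z = radial_zone_labels(d, 0.33)
        np.testing.assert_array_equal(z, [[0, 0, 1, 2]])

    def test_single_zone_when_width_exceeds_max(self):
        d = np.array([[0.1, 0.2], [np.nan, 0.3]])
        z = radial_zone_labels(d, 0.31)
        assert set(z[np.isfinite(d)]) == {0}
        assert z[1, 0] == -1

    def test_zones_partition_tissue(self, disk_image):
        img, truth, spec = disk_image
        d = edge_distance_map(truth["tissue_mask"], spec.pixel_size)
        z = radial_zone_labels(d)
        profile = zone_profile(np.zeros_like(d), np.zeros_like(d, bool), z)
        assert profile.pixel_count.sum() == truth["tissue_mask"].sum()


class TestZoneProfile:
    def test_uniform_positivity(self):
        rng = np.random.default_rng(1)
        z = rng.integers(0, 4, (200, 200))
        pos = rng.random((200, 200)) < 0.37
        profile = zone_profile(np.ones((200, 200)), pos, z)
        assert np.allclose(profile.positive_fraction, 0.37, atol=0.02)

    def test_edge_value_matches_generator(self):
        # deep penetration keeps zone 0 near the programmed edge positivity
        spec = SyntheticIhcSpec(tissue_radius=2.0, pixel_size=0.01,
                                penetration=3.0, edge_positivity=0.8,
                                background_positivity=0.05, seed=12)
        rgb, truth = simulate_ihc_image(spec)
        profile, metrics = quantify_image(StainImage(rgb, spec.pixel_size))
        assert abs(profile.edge_value - 0.8) < 0.05

    def test_counts_equal_zone_areas(self, disk_image):
        img, truth, spec = disk_image
        profile, _ = quantify_image(img)
        d = edge_distance_map(segment_tissue(img), spec.pixel_size)
        z = radial_zone_labels(d)
        for i in range(profile.n_zones):
            assert profile.pixel_count[i] == (z == i).sum()

    def test_threshold_monotonicity(self, disk_image):
        img, _, spec = disk_image
        mask = segment_tissue(img)
        _, dab, _ = unmix(img)
        z = radial_zone_labels(edge_distance_map(mask, spec.pixel_size))
        fracs = []
        for thr in (0.05, 0.15, 0.40):
            fracs.append(zone_profile(dab, dab > thr, z).positive_fraction)
        assert np.all(fracs[0] >= fracs[1]) and np.all(fracs[1] >= fracs[2])


class TestPenetrationDepth:
    def test_worked_example(self):
        profile = ZoneProfile(
            zone_width=0.33,
            pixel_count=np.array([100, 100, 100, 100]),
            positive_fraction=np.array([0.8, 0.7, 0.35, 0.1]),
            mean_dab_od=np.full(4, 0.5),
        )
        depth = penetration_depth(profile)
        assert depth.depth_mm == pytest.approx(0.66)
        assert depth.suppression_detected

    def test_flat_profile_flagged(self):
        profile = ZoneProfile(0.33, np.array([50, 50, 50]),
                              np.array([0.6, 0.62, 0.58]), np.full(3, 0.4))
        depth = penetration_depth(profile)
        assert not depth.suppression_detected
        assert depth.depth_mm == pytest.approx(3 * 0.33)

    @pytest.mark.parametrize("pen", [0.5, 1.0, 1.5])
    def test_end_to_end_recovery(self, pen):
        spec = SyntheticIhcSpec(penetration=pen, edge_positivity=0.9,
                                background_positivity=0.02, seed=3)
        rgb, _ = simulate_ihc_image(spec)
        _, metrics = quantify_image(StainImage(rgb, spec.pixel_size))
        assert abs(metrics["penetration_depth_mm"] - pen) <= 0.33 + 1e-9

    def test_rotation_robustness(self):
        spec = SyntheticIhcSpec(penetration=1.0, edge_positivity=0.9,
                                background_positivity=0.02, seed=3)
        rgb, _ = simulate_ihc_image(spec)
        _, m0 = quantify_image(StainImage(rgb, spec.pixel_size))
        rot = np.rot90(rgb, k=1, axes=(0, 1)).copy()
        _, m1 = quantify_image(StainImage(rot, spec.pixel_size))
        assert abs(m0["penetration_depth_mm"] - m1["penetration_depth_mm"]) <= 0.33

    def test_proper_fraction_monotone_in_penetration(self):
        fracs = []
        for pen in (0.5, 1.0, 1.5):
            spec = SyntheticIhcSpec(penetration=pen, edge_positivity=0.9,
                                    background_positivity=0.02, seed=3)
            rgb, _ = simulate_ihc_image(spec)
            _, metrics = quantify_image(StainImage(rgb, spec.pixel_size))
            fracs.append(metrics["proper_fraction_pct"])
        assert fracs[0] < fracs[1] < fracs[2]


class TestProperStainingFraction:
    def test_worked_examples(self):
        mk = lambda fr: ZoneProfile(0.33, np.full(len(fr), 100),
                                    np.asarray(fr, float), np.full(len(fr), 0.4))
        assert proper_staining_fraction(mk([0.8, 0.6, 0.3])) == pytest.approx(200 / 3)
        assert proper_staining_fraction(mk([0.5, 0.45, 0.4])) == pytest.approx(100.0)
        assert proper_staining_fraction(mk([0.8, 0.1, 0.1, 0.1])) == pytest.approx(25.0)


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        assert res[0].t == 0.0 and res[0].p == 1.0 and not res[0].significant

    def test_closed_form_example(self):
        res = compare_groups({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 3, 4, 5, 6]})[0]
        assert res.t == pytest.approx(-1.0, abs=1e-12)
        assert res.dof == pytest.approx(8.0, abs=1e-12)
        assert res.p == pytest.approx(0.34659350708733416, abs=1e-6)

    def test_matches_scipy_reference(self):
        from scipy import stats as sps

        rng = np.random.default_rng(17)
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(3, 30))
            b = rng.normal(rng.normal(), rng.uniform(0.5, 2), rng.integers(3, 30))
            res = compare_groups({"a": a, "b": b})[0]
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert res.t == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})

    @given(shift=st.floats(-2, 2), n=st.integers(4, 20))
    def test_symmetry(self, shift, n):
        rng = np.random.default_rng(n)
        a = rng.normal(0, 1, n)
        b = a + shift
        r = compare_groups({"a": a, "b": b})[0]
        r2 = compare_groups({"b": b, "a": a})[0]
        assert r.p == pytest.approx(r2.p, rel=1e-12)
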