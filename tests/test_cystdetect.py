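import numpy as np
import pytest
from scipy import ndimage

from cysthead import cystdetect
from cysthead.volio import Volume
from oracles import brute_force_size_filter, sphere_mask


def vol_of(mask, spacing=0.25):
    return Volume(np.asarray(mask), (spacing,) * 3, (0.0, 0.0, 0.0))


class TestBinarize:
    def test_window_is_inclusive_at_both_ends(self):
        v = Volume(np.full((4, 4, 4), 100, dtype=np.uint8), (0.1,) * 3)
        assert cystdetect.binarize_bone(v).values.all()
        v89 = Volume(np.full((4, 4, 4), 89, dtype=np.uint8), (0.1,) * 3)
        assert not cystdetect.binarize_bone(v89, lo=90).values.any()
        v90 = Volume(np.full((4, 4, 4), 90, dtype=np.uint8), (0.1,) * 3)
        assert cystdetect.binarize_bone(v90, lo=90).values.all()

    def test_inverted_window_rejected(self):
        v = Volume(np.zeros((2, 2, 2), dtype=np.uint8), (1,) * 3)
        with pytest.raises(ValueError, match="lo=200 > hi=90"):
            cystdetect.binarize_bone(v, lo=200, hi=90)

    def test_noiseless_phantom_recovers_truth_mask(self):
        """Without blur or noise the 90-255 window reproduces the truth
        bone mask voxel-for-voxel."""
        from cysthead import phantom

        spec = phantom.PhantomSpec(head_radius=5.0, voxel_size=0.25,
                                   noise_sd=0.0, blur_sigma=0.0, seed=2)
        volume, truth = phantom.generate_head(spec)
        mask = cystdetect.binarize_bone(volume)
        np.testing.assert_array_equal(mask.values, truth.bone_mask_truth.values)


class TestTotalRegion:
    def test_idempotent_on_solid_sphere(self):
        m = sphere_mask((40, 40, 40), (19.5,) * 3, 3.5, (0.25,) * 3)
        total = cystdetect.total_region(vol_of(m))
        np.testing.assert_array_equal(total.values, m)

    def test_hollow_shell_fills_to_ball(self):
        outer = sphere_mask((40, 40, 40), (19.5,) * 3, 3.5, (0.25,) * 3)
        inner = sphere_mask((40, 40, 40), (19.5,) * 3, 2.5, (0.25,) * 3)
        total = cystdetect.total_region(vol_of(outer & ~inner))
        np.testing.assert_array_equal(total.values, outer)

    def test_phantom_head_volume_near_analytic(self, head_phantom):
        spec, volume, truth = head_phantom
        bone = cystdetect.binarize_bone(volume)
        total = cystdetect.total_region(bone)
        v = total.values.sum() * total.voxel_volume
        v_analytic = 4 / 3 * np.pi * spec.head_radius**3
        assert v == pytest.approx(v_analytic, rel=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cystdetect.total_region(vol_of(np.zeros((5, 5, 5), dtype=bool)))


class TestEmptyRegions:
    def test_partition_law(self):
        """empty ∪ bone = total and empty ∩ bone = ∅ for arbitrary masks."""
        rng = np.random.default_rng(0)
        total = vol_of(sphere_mask((24, 24, 24), (11.5,) * 3, 2.5, (0.25,) * 3))
        bone = total.like(np.asarray(total.values)
                          & (rng.random((24, 24, 24)) < 0.4))
        empty = cystdetect.empty_regions(total, bone)
        e, b, t = (np.asarray(x.values) for x in (empty, bone, total))
        assert not (e & b).any()
        np.testing.assert_array_equal(e | b, t)

    def test_total_equals_bone_gives_empty(self):
        m = vol_of(sphere_mask((16, 16, 16), (7.5,) * 3, 1.5, (0.25,) * 3))
        assert not cystdetect.empty_regions(m, m).values.any()

    def test_no_bone_returns_whole_total(self):
        t = vol_of(sphere_mask((16, 16, 16), (7.5,) * 3, 1.5, (0.25,) * 3))
        empty = cystdetect.empty_regions(t, t.like(np.zeros_like(t.values)))
        np.testing.assert_array_equal(empty.values, t.values)


class TestSizeFilter:
    def test_sub_threshold_void_removed(self):
        m = sphere_mask((24, 24, 24), (11.5,) * 3, 0.4, (0.1,) * 3)
        out = cystdetect.size_filter(vol_of(m, 0.1))
        assert not out.values.any()

    def test_retained_void_restored_exactly(self):
        m = sphere_mask((32, 32, 32), (15.5,) * 3, 1.0, (0.1,) * 3)
        out = cystdetect.size_filter(vol_of(m, 0.1))
        np.testing.assert_array_equal(out.values, m)

    def test_dumbbell_kept_as_one_component_with_neck(self):
        """Two 2 mm spheres joined by a 0.6 mm neck survive as ONE component
        including the neck: reconstruction refills it."""
        spacing = 0.1
        shape = (64, 32, 32)
        a = sphere_mask(shape, (17, 15.5, 15.5), 1.0, (spacing,) * 3)
        b = sphere_mask(shape, (47, 15.5, 15.5), 1.0, (spacing,) * 3)
        g = np.indices(shape).astype(float)
        neck = (np.sqrt((g[1] - 15.5) ** 2 + (g[2] - 15.5) ** 2) * spacing
                <= 0.3) & (g[0] >= 17) & (g[0] <= 47)
        m = a | b | neck
        out = cystdetect.size_filter(vol_of(m, spacing))
        np.testing.assert_array_equal(out.values, m)
        _, n = ndimage.label(out.values, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        field = ndimage.gaussian_filter(rng.standard_normal((40, 40, 40)), 2.0)
        m = field > np.quantile(field, 0.8)
        once = cystdetect.size_filter(vol_of(m))
        twice = cystdetect.size_filter(once)
        np.testing.assert_array_equal(once.values, twice.values)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_inscribed_sphere_oracle(self, seed):
        """On random void masks the filter equals the brute-force
        largest-inscribed-sphere component filter exactly."""
        rng = np.random.default_rng(seed)
        spacing = 0.25
        field = ndimage.gaussian_filter(rng.standard_normal((32, 32, 32)),
                                        rng.uniform(1.2, 3.0))
        m = field > np.quantile(field, rng.uniform(0.6, 0.85))
        expected = brute_force_size_filter(m, 1.0, 0.5, (spacing,) * 3)
        out = cystdetect.size_filter(vol_of(m, spacing))
        np.testing.assert_array_equal(np.asarray(out.values), expected)

    def test_non_commensurate_step_rejected(self):
        m = vol_of(np.ones((8, 8, 8), dtype=bool))
        with pytest.raises(ValueError, match="integer k"):
            cystdetect.size_filter(m, min_diameter=1.0, step=0.3)


class TestLabelCysts:
    def _total(self, shape=(48, 48, 48), spacing=0.25):
        return vol_of(sphere_mask(shape, tuple((s - 1) / 2 for s in shape),
                                  5.5, (spacing,) * 3), spacing)

    def test_two_disjoint_spheres_two_records(self):
        total = self._total()
        c1 = sphere_mask((48, 48, 48), (18, 23.5, 23.5), 1.0, (0.25,) * 3)
        c2 = sphere_mask((48, 48, 48), (30, 23.5, 23.5), 1.0, (0.25,) * 3)
        labels, records = cystdetect.label_cysts(total.like(c1 | c2), total)
        assert len(records) == 2
        for r in records:
            assert r.volume == pytest.approx(4 / 3 * np.pi, rel=0.1)
            assert not r.touches_exterior

    def test_surface_notch_excluded_by_default(self):
        total = self._total()
        interior = sphere_mask((48, 48, 48), (23.5,) * 3, 1.0, (0.25,) * 3)
        # notch: a void overlapping the head surface
        notch = (sphere_mask((48, 48, 48), (23.5 + 22, 23.5, 23.5), 1.0,
                             (0.25,) * 3) & np.asarray(total.values))
        labels, records = cystdetect.label_cysts(
            total.like(interior | notch), total)
        assert len(records) == 1
        _, all_records = cystdetect.label_cysts(
            total.like(interior | notch), total, include_surface_voids=True)
        assert len(all_records) == 2
        assert sum(r.touches_exterior for r in all_records) == 1

    def test_corner_touching_spheres_connectivity(self):
        """Voxel-corner contact joins under 26-connectivity and splits
        under 6-connectivity."""
        total = self._total()
        m = np.zeros((48, 48, 48), dtype=bool)
        m[20:24, 20:24, 20:24] = True
        m[24:28, 24:28, 24:28] = True
        _, rec26 = cystdetect.label_cysts(total.like(m), total, connectivity=26)
        _, rec6 = cystdetect.label_cysts(total.like(m), total, connectivity=6)
        assert len(rec26) == 1
        assert len(rec6) == 2


class TestSummary:
    def test_panel_arithmetic(self):
        records = [
            cystdetect.CystRecord(1, 4.19, (0, 0, 0), 2.0),
            cystdetect.CystRecord(2, 8.00, (1, 1, 1), 2.5),
        ]
        s = cystdetect.cyst_summary(records)
        assert (s.cyst_n, s.cyst_v) == (2, pytest.approx(12.19))
        assert s.cystv_ave == pytest.approx(6.095)
        assert (s.cystv_min, s.cystv_max) == (4.19, 8.00)
        assert s.cystv_min <= s.cystv_ave <= s.cystv_max

    def test_single_cyst_min_equals_max(self):
        s = cystdetect.cyst_summary(
            [cystdetect.CystRecord(1, 3.0, (0, 0, 0), 1.8)])
        assert s.cystv_min == s.cystv_ave == s.cystv_max == 3.0

    def test_no_cysts_yields_nulls(self):
        s = cystdetect.cyst_summary([])
        assert (s.cyst_n, s.cyst_v) == (0, 0.0)
        assert s.cystv_ave is s.cystv_min is s.cystv_max is None


class TestMineralMap:
    def test_uniform_intensities_split_into_equal_tertiles(self):
        rng = np.random.default_rng(1)
        vals = rng.integers(90, 256, size=(30, 30, 30)).astype(np.uint8)
        v = Volume(vals, (0.1,) * 3)
        bone = v.like(np.ones_like(vals, dtype=bool))
        classes = cystdetect.mineral_map(v, bone).values
        counts = np.bincount(classes.ravel(), minlength=4)[1:]
        assert counts.max() - counts.min() <= 0.02 * vals.size

    def test_outside_mask_is_zero(self):
        vals = np.full((10, 10, 10), 120, dtype=np.uint8)
        vals[5:, :, :] = 200
        v = Volume(vals, (0.1,) * 3)
        bone = v.like(np.zeros_like(vals, dtype=bool))
        bone.values[5:, :, :] = True
        out = cystdetect.mineral_map(v, bone).values
        assert not out[:5].any()

    def test_two_point_distribution_ties_to_lower_class(self):
        """With a half/half two-point distribution both quantile cuts fall
        on the data values; ties route to the lower class."""
        vals = np.full((8, 8, 8), 100, dtype=np.uint8)
        vals[4:, :, :] = 200
        v = Volume(vals, (0.1,) * 3)
        bone = v.like(np.ones_like(vals, dtype=bool))
        classes = cystdetect.mineral_map(v, bone).values
        # q1/3 in (100, 200) -> 100s are class 1; q2/3 = 200 -> 200s class 2
        assert (classes[vals == 100] == 1).all()
        assert (classes[vals == 200] == 2).all()

    def test_constant_bone_warns_all_intermediate(self, caplog):
        vals = np.full((6, 6, 6), 150, dtype=np.uint8)
        v = Volume(vals, (0.1,) * 3)
        bone = v.like(np.ones_like(vals, dtype=bool))
        with caplog.at_level("WARNING"):
            out = cystdetect.mineral_map(v, bone).values
        assert (out == 2).all()


class TestPhantomDetection:
    def test_detects_exactly_the_programmed_cysts(self, head_phantom):
        """Cyst.N equals the specified >1 mm cysts; the 0.8 mm decoy is
        never detected; volumes land within ±10% of analytic."""
        spec, volume, truth = head_phantom
        _, records, summary = cystdetect.detect_cysts(volume)
        detectable = [c for c in spec.cyst_specs if c.diameter > 1.0]
        assert summary.cyst_n == len(detectable)
        for c in detectable:
            rec = min(records, key=lambda r: np.linalg.norm(
                np.asarray(r.centroid) - np.asarray(c.centre)))
            assert np.linalg.norm(
                np.asarray(rec.centroid) - np.asarray(c.centre)) < c.diameter / 2
            assert rec.volume == pytest.approx(
                4 / 3 * np.pi * (c.diameter / 2) ** 3, rel=0.10)

    def test_summary_consistency_invariants(self, head_phantom):
        _, volume, _ = head_phantom
        _, records, s = cystdetect.detect_cysts(volume)
        assert s.cyst_v == pytest.approx(sum(r.volume for r in records))
        assert s.cystv_ave == pytest.approx(s.cyst_v / s.cyst_n)
        assert s.cystv_min <= s.cystv_ave <= s.cystv_max
        for r in records:
            assert r.max_inscribed_diameter > 1.0
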