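import numpy as np
import pytest

from spectharm import (
    AcquisitionSettings,
    CalibrationResult,
    NoContrastError,
    QuantImage,
    SphereSpec,
    UNIT_COUNTS,
    UNIT_KBQ_PER_ML,
    VOIMask,
    compute_background_rc,
    compute_cf,
    compute_rc,
    counts_to_concentration,
    cylinder_roi,
    place_background_vois,
    segment_sphere,
)


def make_image(grid, voxel=4.8, unit=UNIT_COUNTS, t=20.0, n=128):
    grid = np.asarray(grid, dtype=float)
    h = np.full(3, float(voxel))
    origin = -(np.asarray(grid.shape) - 1) / 2.0 * h
    return QuantImage(
        grid=grid, voxel_size_mm=h, origin_mm=origin, unit=unit,
        settings=AcquisitionSettings(n_projections=n, time_per_projection_s=t),
    )


def full_roi(image, kind="background_cylinder", label="all"):
    return VOIMask(indices=np.argwhere(np.ones(image.grid.shape, bool)), kind=kind, label=label)


def hard_sphere_image(radius_mm=18.5, inner=100.0, outer=10.0, voxel=4.8, n=41,
                      unit=UNIT_KBQ_PER_ML):
    img = make_image(np.full((n, n, n), outer), voxel=voxel, unit=unit)
    x, y, z = img.axis_coords()
    d2 = (x**2)[:, None, None] + (y**2)[None, :, None] + (z**2)[None, None, :]
    img.grid[d2 <= radius_mm**2] = inner
    return img


class TestComputeCF:
    def test_identity_construction(self):
        # mu = t*n*nu*A exactly -> cf = 1
        t, n, voxel, A = 20.0, 128, 4.8, 0.5
        nu = voxel**3 * 1e-3
        img = make_image(np.full((6, 6, 6), t * n * nu * A), voxel=voxel, t=t, n=n)
        cal = compute_cf(img, full_roi(img), A)
        assert cal.cf == pytest.approx(1.0, rel=1e-12)
        # algebraic identity cf*A*t*n*nu = mu
        assert cal.cf * A * t * n * nu == pytest.approx(cal.mean_voxel_value, rel=1e-12)

    def test_hand_arithmetic(self):
        # mu=2560, t=20, n=128, nu=0.1 ml -> count rate density 10 cps/ml;
        # at A=100 kBq/ml the CF is 0.1 (cps/ml)/(kBq/ml)
        img = make_image(np.full((4, 4, 4), 2560.0), voxel=0.1**(1 / 3) * 10, t=20.0, n=128)
        assert img.voxel_volume_ml == pytest.approx(0.1)
        cal = compute_cf(img, full_roi(img), 100.0)
        assert cal.cf == pytest.approx(0.1, rel=1e-9)

    def test_errors(self):
        img = make_image(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            compute_cf(img, full_roi(img), 0.0)
        with pytest.raises(ValueError):
            compute_cf(img, VOIMask(indices=np.empty((0, 3), int), kind="background_cylinder",
                                    label="empty"), 10.0)
        conc = make_image(np.ones((4, 4, 4)), unit=UNIT_KBQ_PER_ML)
        with pytest.raises(ValueError):
            compute_cf(conc, full_roi(conc), 10.0)


class TestCountsToConcentration:
    def test_algebraic_inverse(self):
        rng = np.random.default_rng(0)
        counts = make_image(rng.uniform(0, 500, (8, 8, 8)))
        cal = CalibrationResult.from_factor(0.0951, 20.0, 128, counts.voxel_volume_ml)
        conc = counts_to_concentration(counts, cal)
        assert conc.unit == UNIT_KBQ_PER_ML
        back = conc.grid * (cal.cf * 20.0 * 128 * counts.voxel_volume_ml)
        np.testing.assert_allclose(back, counts.grid, rtol=1e-9)

    def test_zero_and_linearity(self):
        zero = make_image(np.zeros((5, 5, 5)))
        cal = CalibrationResult.from_factor(0.1, 20.0, 128, zero.voxel_volume_ml)
        assert np.all(counts_to_concentration(zero, cal).grid == 0)
        img = make_image(np.full((5, 5, 5), 300.0))
        c1 = counts_to_concentration(img, cal).grid
        c2 = counts_to_concentration(
            img, CalibrationResult.from_factor(0.2, 20.0, 128, img.voxel_volume_ml)
        ).grid
        np.testing.assert_allclose(c2, c1 / 2.0, rtol=1e-12)
        with pytest.raises(ValueError):
            CalibrationResult.from_factor(-1.0, 20.0, 128, 0.1)


class TestBackgroundVOIs:
    def test_uniform_value_and_geometry(self, small_spec):
        img = make_image(np.full((71, 57, 44), 7.25), unit=UNIT_KBQ_PER_ML)
        vois, vv_bg = place_background_vois(img, small_spec)
        assert len(vois) == 6
        assert vv_bg == 7.25
        # pairwise disjoint
        sets = [set(map(tuple, m.indices)) for m in vois]
        for i in range(6):
            for j in range(i + 1, 6):
                assert not sets[i] & sets[j]
        # every VOI voxel keeps >= 15 mm from every sphere surface
        x, y, z = img.axis_coords()
        for m in vois:
            px = x[m.indices[:, 0]]; py = y[m.indices[:, 1]]; pz = z[m.indices[:, 2]]
            for s in small_spec.spheres:
                cx, cy, cz = s.center_mm
                d = np.sqrt((px - cx) ** 2 + (py - cy) ** 2 + (pz - cz) ** 2) - s.radius_mm
                assert d.min() >= 15.0 - 1e-9
            # and strictly inside the body outline
            assert np.all(small_spec.body.sdf(px, py, pz) < 0)

    def test_impossible_placement_raises(self, small_spec):
        img = make_image(np.full((71, 57, 44), 1.0), unit=UNIT_KBQ_PER_ML)
        from spectharm import PlacementError

        with pytest.raises(PlacementError):
            place_background_vois(img, small_spec, height_cm=20.0)  # no axial room


class TestSegmentSphere:
    def test_hard_edged_sphere_exact_support(self):
        """Hard 100-on-10 sphere: threshold 0.5*(100+10)=55, mask = support."""
        img = hard_sphere_image()
        sphere = SphereSpec(label="s37", inner_diameter_mm=37, center_mm=(0, 0, 0),
                            activity_kbq_per_ml=100)
        mask = segment_sphere(img, sphere, vv_mean_bg=10.0)
        assert mask.threshold_used == pytest.approx(55.0)
        expected = np.argwhere(img.grid == 100.0)
        assert set(map(tuple, mask.indices)) == set(map(tuple, expected))

    def test_no_contrast_failure(self):
        img = make_image(np.full((21, 21, 21), 10.0), unit=UNIT_KBQ_PER_ML)
        sphere = SphereSpec(label="s10", inner_diameter_mm=10, center_mm=(0, 0, 0),
                            activity_kbq_per_ml=100)
        with pytest.raises(NoContrastError):
            segment_sphere(img, sphere, vv_mean_bg=10.0)

    def test_out_of_bounds_search_region(self):
        img = hard_sphere_image(n=9)
        sphere = SphereSpec(label="far", inner_diameter_mm=10, center_mm=(100, 0, 0),
                            activity_kbq_per_ml=100)
        with pytest.raises(ValueError, match="bounds"):
            segment_sphere(img, sphere, vv_mean_bg=10.0)

    def test_zero_background_reduces_to_half_max(self):
        """With zero background the threshold is exactly 50% of the max."""
        img = hard_sphere_image(inner=80.0, outer=0.0)
        sphere = SphereSpec(label="s", inner_diameter_mm=37, center_mm=(0, 0, 0),
                            activity_kbq_per_ml=80)
        mask = segment_sphere(img, sphere, vv_mean_bg=0.0)
        assert mask.threshold_used == pytest.approx(0.5 * 80.0)
        half_max = np.argwhere(img.grid >= 40.0)
        assert set(map(tuple, mask.indices)) == set(map(tuple, half_max))


class TestRecoveryCoefficients:
    def test_constant_region(self):
        img = make_image(np.full((9, 9, 9), 50.0), unit=UNIT_KBQ_PER_ML)
        rec = compute_rc(full_roi(img, kind="sphere"), img, 50.0, sphere_diameter_mm=28)
        assert rec.rc_mean == pytest.approx(1.0) and rec.rc_max == pytest.approx(1.0)
        rec = compute_rc(full_roi(img, kind="sphere"), img, 50.0 / 0.9)
        assert rec.rc_mean == pytest.approx(0.9)
        assert rec.voi_volume_ml == pytest.approx(9**3 * 4.8**3 * 1e-3)

    def test_rc_max_bounds_rc_mean(self):
        rng = np.random.default_rng(1)
        img = make_image(rng.uniform(1, 5, (7, 7, 7)), unit=UNIT_KBQ_PER_ML)
        rec = compute_rc(full_roi(img, kind="sphere"), img, 3.0)
        assert rec.rc_max >= rec.rc_mean > 0

    def test_unit_mismatch_rejected(self):
        img = make_image(np.ones((5, 5, 5)), unit=UNIT_COUNTS)
        with pytest.raises(ValueError):
            compute_rc(full_roi(img), img, 10.0)

    def test_scale_invariance_of_segmentation_and_rc(self):
        """Rescaling the image together with A leaves the RC unchanged."""
        img = hard_sphere_image(radius_mm=11.0, inner=90.0, outer=9.0)
        sphere = SphereSpec(label="s22", inner_diameter_mm=22, center_mm=(0, 0, 0),
                            activity_kbq_per_ml=90)
        for factor in (1.0, 3.7):
            scaled = make_image(img.grid * factor, unit=UNIT_KBQ_PER_ML)
            mask = segment_sphere(scaled, sphere, vv_mean_bg=9.0 * factor)
            rec = compute_rc(mask, scaled, 90.0 * factor, sphere_diameter_mm=22)
            assert rec.rc_mean == pytest.approx(1.0)
            assert mask.n_voxels == segment_sphere(img, sphere, 9.0).n_voxels


class TestBackgroundRC:
    def test_trivial_values(self, small_spec):
        img = make_image(np.full((71, 57, 44), 10.0), unit=UNIT_KBQ_PER_ML)
        vois, _ = place_background_vois(img, small_spec)
        assert compute_background_rc(img, vois, 10.0) == pytest.approx(1.0)
        zero = make_image(np.zeros((71, 57, 44)), unit=UNIT_KBQ_PER_ML)
        assert compute_background_rc(zero, vois, 10.0) == 0.0

    def test_cylinder_roi(self):
        img = make_image(np.full((21, 21, 21), 3.0), unit=UNIT_COUNTS)
        roi = cylinder_roi(img, (0, 0, 0), radius_mm=20.0, height_mm=30.0)
        assert roi.n_voxels > 0
        x, y, z = img.axis_coords()
        px = x[roi.indices[:, 0]]; py = y[roi.indices[:, 1]]; pz = z[roi.indices[:, 2]]
        assert np.all(px**2 + py**2 <= 20.0**2 + 1e-9)
        assert np.all(np.abs(pz) <= 15.0 + 1e-9)
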