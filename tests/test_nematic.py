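"""Nematic order parameter, autocorrelation and defect detection tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from fiberorder import (
    CorrelationProfile,
    FiberPatternSpec,
    Mask,
    angle_autocorrelation,
    correlation_length,
    detect_defects,
    local_order_parameter,
    make_director_field,
    mean_order,
)
from fiberorder.nematic import total_charge_on_charts


def _field(theta_deg, angle_field):
    return angle_field(np.asarray(theta_deg, dtype=float))


class TestLocalOrderParameter:
    def test_constant_angle_gives_unity(self, angle_field, full_mask):
        o = _field(np.full((16, 16), 30.0), angle_field)
        S = local_order_parameter(o, full_mask((16, 16)), 8.0, exclude_border=False).S
        np.testing.assert_allclose(S, 1.0, atol=1e-9)

    def test_equal_orthogonal_weights_cancel(self, angle_field, full_mask):
        # equal numbers of 0° and 90° in every window: resultant of (1,0), (−1,0)
        theta = np.zeros((8, 8))
        theta[4:] = 90.0
        o = _field(theta, angle_field)
        # kernel radius larger than the field: every window sees all pixels
        S = local_order_parameter(o, full_mask((8, 8)), 40.0, exclude_border=False).S
        np.testing.assert_allclose(S, 0.0, atol=1e-9)

    def test_two_thirds_zero_one_third_45(self, angle_field, full_mask):
        # ⟨cos2θ⟩ = 2/3, ⟨sin2θ⟩ = 1/3 → S = sqrt(5)/3
        theta = np.zeros((6, 6))
        theta[4:] = 45.0
        o = _field(theta, angle_field)
        S = local_order_parameter(o, full_mask((6, 6)), 40.0, exclude_border=False).S
        np.testing.assert_allclose(S, np.sqrt(5) / 3, atol=1e-9)

    def test_matches_bruteforce_oracle(self, angle_field):
        rng = np.random.default_rng(10)
        theta = rng.uniform(0, 180, (48, 48))
        valid = rng.random((48, 48)) > 0.2
        o = _field(theta, angle_field)
        mask = Mask(valid, 1.0)
        prod = local_order_parameter(o, mask, 9.0, exclude_border=False).S
        ref = oracles.windowed_order_bruteforce(theta, valid, 4.5)
        both = np.isfinite(prod) & np.isfinite(ref)
        assert np.array_equal(np.isfinite(prod), np.isfinite(ref))
        assert np.max(np.abs(prod[both] - ref[both])) < 1e-10

    def test_uniform_random_angles_near_zero(self, angle_field, full_mask):
        rng = np.random.default_rng(5)
        o = _field(rng.uniform(0, 180, (128, 128)), angle_field)
        field = local_order_parameter(o, full_mask((128, 128)), 40.0,
                                      exclude_border=False)
        assert mean_order(field) <= 0.1

    def test_window_outside_mask_is_undefined(self, angle_field):
        theta = np.zeros((32, 32))
        mask = np.zeros((32, 32), dtype=bool)
        mask[:8, :8] = True
        field = local_order_parameter(_field(theta, angle_field), Mask(mask, 1.0),
                                      6.0, exclude_border=False)
        assert np.isnan(field.S[24, 24])
        assert field.S[4, 4] == pytest.approx(1.0)

    def test_too_small_window_rejected(self, angle_field, full_mask):
        with pytest.raises(ValueError, match="5 pixels"):
            local_order_parameter(_field(np.zeros((16, 16)), angle_field),
                                  full_mask((16, 16)), 3.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        shift=st.floats(0, 180),
        seed=st.integers(0, 2**16),
    )
    def test_invariant_under_global_rotation_and_nematic_flip(self, shift, seed):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 180, (20, 20))
        ones = np.ones_like(theta)
        from fiberorder import OrientationField

        mask = Mask.full((20, 20), 1.0)
        base = local_order_parameter(
            OrientationField(theta, ones, ones, 1.0), mask, 8.0, exclude_border=False
        ).S
        rotated = local_order_parameter(
            OrientationField((theta + shift) % 180, ones, ones, 1.0),
            mask, 8.0, exclude_border=False,
        ).S
        np.testing.assert_allclose(base, rotated, atol=1e-9)
        assert np.nanmin(base) >= 0 and np.nanmax(base) <= 1


class TestMeanOrder:
    def test_constant_field(self, angle_field, full_mask):
        from fiberorder import OrderField

        field = OrderField(np.full((10, 10), 0.5), 8.0, 1.0)
        assert mean_order(field) == pytest.approx(0.5)

    def test_half_low_half_high(self):
        from fiberorder import OrderField

        S = np.full((10, 10), 0.2)
        S[5:] = 0.8
        assert mean_order(OrderField(S, 8.0, 1.0)) == pytest.approx(0.5)

    def test_no_defined_pixels_raises(self):
        from fiberorder import OrderField

        with pytest.raises(ValueError, match="no defined"):
            mean_order(OrderField(np.full((4, 4), np.nan), 8.0, 1.0))


class TestAutocorrelation:
    def test_constant_field_fully_correlated(self, angle_field, full_mask):
        o = _field(np.full((24, 24), 72.0), angle_field)
        prof = angle_autocorrelation(o, full_mask((24, 24)), dr_um=2.0, r_max_um=12.0,
                                     seed=0, exclude_border=False)
        defined = np.isfinite(prof.C)
        np.testing.assert_allclose(prof.C[defined], 1.0, atol=1e-12)

    def test_alternating_columns_anticorrelated_at_one_pixel(self, angle_field):
        # single-row mask restricts pairs to x-lags; adjacent columns 0°/90°
        theta = np.zeros((9, 64))
        theta[:, 1::2] = 90.0
        mask = np.zeros((9, 64), dtype=bool)
        mask[4] = True
        prof = angle_autocorrelation(_field(theta, angle_field), Mask(mask, 1.0),
                                     dr_um=0.5, r_max_um=4.0, seed=0,
                                     exclude_border=False)
        k = np.searchsorted(prof.r_um, 1.25)  # bin [1.0, 1.5)
        assert prof.C[k] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_allpairs_bruteforce(self, angle_field):
        rng = np.random.default_rng(2)
        theta = rng.uniform(0, 180, (20, 20))
        valid = rng.random((20, 20)) > 0.3
        o = _field(theta, angle_field)
        prof = angle_autocorrelation(o, Mask(valid, 1.0), dr_um=1.5, r_max_um=15.0,
                                     seed=0, exclude_border=False)
        r_ref, c_ref = oracles.autocorrelation_bruteforce(theta, valid, 1.0, 1.5, 15.0)
        np.testing.assert_allclose(prof.r_um, r_ref)
        both = np.isfinite(prof.C) & np.isfinite(c_ref)
        assert np.array_equal(np.isfinite(prof.C), np.isfinite(c_ref))
        assert np.max(np.abs(prof.C[both] - c_ref[both])) < 1e-10

    def test_mosaic_correlation_decays_on_domain_scale(self, angle_field, full_mask):
        rng = np.random.default_rng(0)
        shape = (160, 160)
        pts = rng.uniform([0, 0], shape, size=(16, 2))
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        dm = np.argmin((yy[..., None] - pts[:, 0]) ** 2
                       + (xx[..., None] - pts[:, 1]) ** 2, axis=-1) + 1
        spec = FiberPatternSpec(image_shape=shape, pixel_size_um=1.0,
                                director_mode="mosaic", domain_map=dm, seed=4)
        o = _field(make_director_field(spec), angle_field)
        prof = angle_autocorrelation(o, full_mask(shape), dr_um=4.0, r_max_um=120.0,
                                     seed=1, n_points_max=1200, exclude_border=False)
        length, _, censored = correlation_length(prof, 0.2)
        assert not censored
        domain_scale = np.sqrt(shape[0] * shape[1] / 16)
        assert 0.3 * domain_scale < length < 3.0 * domain_scale


class TestCorrelationLength:
    def test_linear_interpolation(self):
        prof = CorrelationProfile(
            r_um=np.array([0.0, 10.0, 20.0]), C=np.array([1.0, 0.5, 0.1]),
            n_pairs=np.array([0, 10, 10]), dr_um=10.0,
        )
        length, norm, censored = correlation_length(prof, 0.2, diameter_um=100.0)
        assert length == pytest.approx(17.5)
        assert norm == pytest.approx(0.175)
        assert not censored

    def test_never_crossing_is_censored_at_r_max(self):
        prof = CorrelationProfile(
            r_um=np.array([0.0, 5.0, 10.0]), C=np.array([1.0, 0.9, 0.8]),
            n_pairs=np.array([0, 5, 5]), dr_um=5.0,
        )
        length, _, censored = correlation_length(prof, 0.2)
        assert censored and length == pytest.approx(10.0)

    def test_threshold_one_crosses_at_origin(self):
        prof = CorrelationProfile(
            r_um=np.array([0.0, 5.0]), C=np.array([1.0, 0.5]),
            n_pairs=np.array([0, 5]), dr_um=5.0,
        )
        length, _, censored = correlation_length(prof, 1.0)
        assert length == 0.0 and not censored

    def test_single_bin_raises(self):
        prof = CorrelationProfile(r_um=np.array([0.0]), C=np.array([1.0]),
                                  n_pairs=np.array([0]), dr_um=1.0)
        with pytest.raises(ValueError, match="2 defined"):
            correlation_length(prof)


class TestDefectDetection:
    @pytest.mark.parametrize("charge", [0.5, -0.5, 1.0, -1.0])
    def test_single_defect_charge_and_position(self, charge, angle_field, full_mask):
        spec = FiberPatternSpec(image_shape=(96, 96), director_mode="defect",
                                defects=[(48, 48, charge)])
        o = _field(make_director_field(spec), angle_field)
        found = detect_defects(o, full_mask((96, 96)))
        assert len(found.defects) == 1
        r, c, s = found.defects[0]
        assert s == charge
        assert abs(r - 48) < 3 and abs(c - 48) < 3

    def test_planar_total_charge_equals_constructed_sum(self, angle_field, full_mask):
        spec = FiberPatternSpec(
            image_shape=(128, 128), director_mode="defect",
            defects=[(40, 40, 0.5), (88, 88, 0.5), (40, 88, -0.5)],
        )
        o = _field(make_director_field(spec), angle_field)
        found = detect_defects(o, full_mask((128, 128)))
        assert found.total_charge == pytest.approx(0.5)
        assert sorted(found.charges()) == [-0.5, 0.5, 0.5]

    def test_sphere_charts_total_charge_plus_two(self, angle_field, full_mask):
        # two stereographic charts, one +1 boojum-like defect per pole
        charts = []
        for theta0 in (0.0, 90.0):
            spec = FiberPatternSpec(image_shape=(96, 96), director_mode="defect",
                                    base_angle_deg=theta0, defects=[(48, 48, 1.0)])
            charts.append((_field(make_director_field(spec), angle_field),
                           full_mask((96, 96))))
        assert total_charge_on_charts(charts) == 2.0

    def test_defect_free_field_empty(self, angle_field, full_mask):
        o = _field(np.full((64, 64), 25.0), angle_field)
        assert detect_defects(o, full_mask((64, 64))).defects == []

    def test_loop_radius_validation(self, angle_field, full_mask):
        o = _field(np.zeros((16, 16)), angle_field)
        with pytest.raises(ValueError, match="loop radius"):
            detect_defects(o, full_mask((16, 16)), loop_radius_px=0.5)
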