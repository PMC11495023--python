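import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from csfflow import (
    AcquisitionMeta,
    PhaseSeries,
    RoiMask,
    correct_aliasing,
    estimate_bias,
    mean_velocity_curve,
    noise_flagged,
    subtract_bias,
    to_velocity,
)
from csfflow.phantom import wrap_velocity

from conftest import make_field


def make_series(raw, meta, allow_overrange=False):
    """PhaseSeries whose first pixels hold the given (n_frames, n_pix) values."""
    raw = np.asarray(raw, dtype=float)
    frames = np.zeros((meta.n_frames, 64, 64))
    n_pix = raw.shape[1]
    rows = [i // 64 for i in range(n_pix)]
    cols = [i % 64 for i in range(n_pix)]
    frames[:, rows, cols] = raw
    mask = RoiMask(pixels=tuple(zip(rows, cols)), kind="target", shape=(64, 64))
    return PhaseSeries(frames=frames, meta=meta, allow_overrange=allow_overrange), mask


class TestToVelocity:
    @pytest.mark.parametrize(
        "raw,expected",
        [(100.0, 10.0), (0.0, 0.0), (-50.0, -5.0)],  # endpoints and linearity
    )
    def test_linear_map(self, meta, raw, expected):
        series, mask = make_series(np.full((8, 1), raw), meta)
        field = to_velocity(series, mask)
        assert field.velocities == pytest.approx(expected, abs=1e-12)
        assert field.corrections_applied == ("venc_scaling",)

    @settings(deadline=None, max_examples=25,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(k=st.floats(-1.0, 1.0), raw=st.floats(-100.0, 100.0))
    def test_linearity_property(self, meta, k, raw):
        s1, mask = make_series(np.full((8, 1), raw), meta)
        s2, _ = make_series(np.full((8, 1), k * raw), meta)
        v1 = to_velocity(s1, mask).velocities
        v2 = to_velocity(s2, mask).velocities
        np.testing.assert_allclose(v2, k * v1, atol=1e-9)


class TestEstimateBias:
    def test_constant_field(self, meta):
        field = make_field(np.full((8, 5), 2.5), meta, kind="reference")
        bias = estimate_bias(field)
        assert bias.value == pytest.approx(2.5, abs=1e-12)
        assert bias.noise_spread == 0.0

    def test_zero_mean_noise_converges(self, meta):
        # 10^4 Gaussian draws: the estimate lands within 3 sigma/sqrt(n) of 0
        rng = np.random.default_rng(11)
        sigma = 1.0
        n = 8 * 1250
        field = make_field(rng.normal(0, sigma, size=(8, 1250)), meta, kind="reference")
        bias = estimate_bias(field)
        assert abs(bias.value) < 3 * sigma / np.sqrt(n)
        assert bias.noise_spread == pytest.approx(sigma, rel=0.05)

    def test_sinusoid_over_frames_averages_out(self, meta):
        # c + zero-mean sinusoid over a full cycle has global mean c
        c = 0.7
        t = meta.frame_times()
        curve = c + 1.3 * np.sin(2 * np.pi * t / meta.cycle_duration)
        field = make_field(np.tile(curve[:, None], (1, 4)), meta, kind="reference")
        bias = estimate_bias(field, mode="global")
        assert bias.value == pytest.approx(c, abs=1e-12)

    def test_per_frame_mode_tracks_frame_means(self, meta):
        rng = np.random.default_rng(5)
        v = rng.normal(0, 1, size=(8, 10))
        field = make_field(v, meta, kind="reference")
        bias = estimate_bias(field, mode="per_frame")
        np.testing.assert_allclose(bias.reference_mean_curve, v.mean(axis=1), atol=1e-14)
        assert bias.value == pytest.approx(v.mean(axis=1).mean(), abs=1e-14)

    def test_requires_reference_mask(self, meta):
        field = make_field(np.zeros((8, 3)), meta, kind="target")
        with pytest.raises(ValueError, match="reference"):
            estimate_bias(field)


class TestSubtractBias:
    def test_inverse_of_constant_shift(self, meta):
        rng = np.random.default_rng(2)
        v = rng.normal(0, 2, size=(8, 6))
        c = 1.7
        shifted = make_field(v + c, meta, corrected=False)
        ref = make_field(np.full((8, 20), c), meta, kind="reference")
        out = subtract_bias(shifted, estimate_bias(ref))
        np.testing.assert_allclose(out.velocities, v, atol=1e-12)

    def test_zero_bias_is_identity(self, meta):
        v = np.arange(16.0).reshape(8, 2)
        field = make_field(v, meta, corrected=False)
        ref = make_field(np.zeros((8, 4)), meta, kind="reference")
        out = subtract_bias(field, estimate_bias(ref))
        np.testing.assert_array_equal(out.velocities, v)

    def test_double_application_rejected(self, meta):
        field = make_field(np.zeros((8, 2)), meta, corrected=False)
        ref = make_field(np.zeros((8, 4)), meta, kind="reference")
        bias = estimate_bias(ref)
        once = subtract_bias(field, bias)
        with pytest.raises(ValueError, match="already applied"):
            subtract_bias(once, bias)

    def test_per_frame_mode_subtracts_frame_curve(self, meta):
        rng = np.random.default_rng(9)
        ref_v = rng.normal(0.5, 1, size=(8, 30))
        csf_v = rng.normal(0, 3, size=(8, 5))
        ref = make_field(ref_v, meta, kind="reference")
        bias = estimate_bias(ref, mode="per_frame")
        out = subtract_bias(make_field(csf_v, meta, corrected=False), bias)
        np.testing.assert_allclose(
            out.velocities, csf_v - ref_v.mean(axis=1)[:, None], atol=1e-14
        )

    def test_mean_curve_commutes_with_bias_subtraction(self, meta):
        rng = np.random.default_rng(4)
        v = rng.normal(0, 2, size=(8, 7))
        field = make_field(v, meta, corrected=False)
        ref = make_field(rng.normal(1.0, 0.5, size=(8, 40)), meta, kind="reference")
        bias = estimate_bias(ref)
        np.testing.assert_allclose(
            mean_velocity_curve(subtract_bias(field, bias)),
            mean_velocity_curve(field) - bias.value,
            atol=1e-12,
        )


class TestCorrectAliasing:
    def test_single_wrapped_peak_restored(self, meta):
        # true peak 1.5*VENC stored wrapped as -0.5*VENC
        venc = meta.venc
        t = meta.frame_times()
        true = 15.0 * np.sin(np.pi * t / meta.cycle_duration) ** 2  # peak 1.5*VENC
        wrapped = wrap_velocity(true, venc)
        assert wrapped.min() < 0  # the peak did wrap
        field = make_field(wrapped[:, None], meta, corrected=False)
        out = correct_aliasing(field)
        np.testing.assert_allclose(out.velocities[:, 0], true, atol=1e-9)

    def test_unaliased_field_unchanged(self, meta):
        rng = np.random.default_rng(8)
        v = rng.uniform(-4, 4, size=(8, 3))  # |v| < VENC and jumps < VENC
        v.sort(axis=0)  # keeps consecutive jumps small
        field = make_field(v, meta, corrected=False)
        out = correct_aliasing(field)
        np.testing.assert_array_equal(out.velocities, v)
        assert "aliasing_correction" in out.corrections_applied

    @settings(deadline=None, max_examples=30,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(st.integers(0, 2**31 - 1))
    def test_idempotence(self, meta, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(-15, 15, size=(8, 2))
        field = make_field(v, meta, corrected=False)
        once = correct_aliasing(field)
        twice = correct_aliasing(once)
        np.testing.assert_array_equal(once.velocities, twice.velocities)
        assert once.corrections_applied == twice.corrections_applied

    def test_jumps_bounded_after_correction(self, meta):
        rng = np.random.default_rng(13)
        v = rng.uniform(-9.9, 9.9, size=(8, 4))
        out = correct_aliasing(make_field(v, meta, corrected=False))
        jumps = np.abs(np.diff(out.velocities, axis=0))
        assert np.all(jumps <= meta.venc + 1e-12)


class TestMeanVelocityCurve:
    def test_single_pixel_roi(self, meta):
        v = np.linspace(-3, 3, 8)[:, None]
        field = make_field(v, meta)
        np.testing.assert_array_equal(mean_velocity_curve(field), v[:, 0])

    def test_antisymmetric_pixels_cancel(self, meta):
        v = np.linspace(-3, 3, 8)
        field = make_field(np.column_stack([v, -v]), meta)
        np.testing.assert_allclose(mean_velocity_curve(field), 0.0, atol=1e-14)

    def test_parabolic_profile_mean_is_half_centre(self):
        # Poiseuille profile: continuum spatial mean = v_c/2; pixelation
        # error measured on a 200x200 grid is ~1e-4
        meta = AcquisitionMeta(
            venc=10, dx=0.05, dy=0.05, n_frames=4, cycle_duration=1.0, raw_scale=100
        )
        v_c = 6.0
        rr, cc = np.mgrid[0:200, 0:200]
        r2 = (rr - 100.0) ** 2 + (cc - 100.0) ** 2
        R = 95.0
        inside = r2 <= R**2
        profile = v_c * (1 - r2[inside] / R**2)
        pixels = tuple(zip(*np.nonzero(inside)))
        mask = RoiMask(pixels=pixels, kind="target", shape=(200, 200))
        from csfflow.velocity import VelocityField, CORRECTIONS

        field = VelocityField(
            velocities=np.tile(profile, (4, 1)),
            times=meta.frame_times(),
            mask=mask,
            meta=meta,
            corrections_applied=CORRECTIONS,
        )
        curve = mean_velocity_curve(field)
        assert curve == pytest.approx(v_c / 2, abs=1e-3 * v_c)


class TestNoiseFlag:
    def test_quiet_field_flagged_pulsatile_field_not(self, meta):
        t = meta.frame_times()
        pulse = 3.0 * np.sin(2 * np.pi * t / meta.cycle_duration)
        ref = make_field(
            np.random.default_rng(1).normal(0, 0.5, size=(8, 40)),
            meta,
            kind="reference",
        )
        bias = estimate_bias(ref)
        strong = make_field(np.tile(pulse[:, None], (1, 26)), meta)
        weak = make_field(np.full((8, 26), 1e-4), meta)
        assert not noise_flagged(strong, bias)
        assert noise_flagged(weak, bias)
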