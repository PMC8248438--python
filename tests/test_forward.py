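"""Forward model: unit conversion, masks, spectral diffusion, sequences."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frapkit import (
    BleachRegion,
    ExperimentProtocol,
    SampleParams,
    d_star_from_si,
    d_star_to_si,
    default_protocol,
    diffuse,
    extract_recovery_curve,
    make_bleach_mask,
    make_roi_weights,
    model_recovery_curve,
    simulate_recovery_curve,
    simulate_sequence,
)


class TestUnitConversion:
    @pytest.mark.parametrize("d_si, expected", [
        (1e-12, 0.2386),   # lower prior edge at the standard pixel size
        (1e-9, 3.2386),    # upper prior edge
    ])
    def test_standard_pixel_size_endpoints(self, d_si, expected):
        assert d_star_from_si(d_si, 0.7598) == pytest.approx(expected, abs=5e-5)

    @given(st.floats(min_value=-13, max_value=-8),
           st.floats(min_value=0.1, max_value=5.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_round_trip(self, log_d, px):
        d_si = 10.0**log_d
        assert d_star_to_si(d_star_from_si(d_si, px), px) == pytest.approx(
            d_si, rel=1e-12)

    @pytest.mark.parametrize("d_si, px", [(0.0, 1.0), (-1e-12, 1.0), (1e-12, 0.0)])
    def test_rejects_non_positive(self, d_si, px):
        with pytest.raises(ValueError):
            d_star_from_si(d_si, px)


class TestBleachMask:
    def test_alpha_one_is_identity_mask(self, proto64):
        assert np.all(make_bleach_mask(proto64, 1.0) == 1.0)

    def test_interior_and_exterior_limits(self):
        proto = ExperimentProtocol(
            n_side=64, padding=32,
            bleach_region=BleachRegion(shape="circle", center=(31.5, 31.5),
                                       radius=19.74 / 2))
        mask = make_bleach_mask(proto, 0.5)
        g = proto.padding + 31  # near the region center on the padded grid
        assert mask[g, g] == 0.5
        # a pixel two radii away from the center is fully outside
        far = proto.padding + 31 + int(2 * 9.87) + 2
        assert mask[g, far] == 1.0
        assert mask.min() >= 0.5 and mask.max() <= 1.0

    def test_edge_pixel_matches_supersampling_oracle(self, proto64):
        """Edge value = alpha + (1-alpha)*(1-coverage), coverage from an
        independent 16x16 subpixel count."""
        alpha = 0.4
        mask = make_bleach_mask(proto64, alpha)
        reg = proto64.bleach_region
        xc, yc = reg.resolved_center(proto64.n_side)
        xc += proto64.padding
        yc += proto64.padding
        # scan the +x axis for a pixel genuinely straddling the circle edge
        sub = (np.arange(16) + 0.5) / 16 - 0.5
        checked = 0
        for px in range(int(xc), int(xc) + 2 * int(reg.radius)):
            for py in (int(yc), int(yc) + 3):
                cov = sum((((px + dx - xc) ** 2 + (py + dy - yc) ** 2)
                           <= reg.radius**2)
                          for dx in sub for dy in sub) / 256.0
                if 0 < cov < 1:
                    assert mask[py, px] == pytest.approx(
                        alpha + (1 - alpha) * (1 - cov), abs=1e-12)
                    checked += 1
        assert checked >= 2, "no edge pixels found along the scan"

    def test_region_outside_fov_rejected(self):
        with pytest.raises(ValueError):
            ExperimentProtocol(
                n_side=64, padding=32,
                bleach_region=BleachRegion(shape="circle", center=(2.0, 2.0),
                                           radius=10.0))


class TestRoiWeights:
    def test_normalization(self, proto64, proto128):
        for proto in (proto64, proto128):
            m = make_roi_weights(proto)
            assert m.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(m >= 0)

    def test_standard_disk_pixel_count(self):
        """A 30 um disk at 0.7598 um/px covers ~pi*(15/0.7598)^2 = 1224 px."""
        proto = default_protocol(128)
        m = make_roi_weights(proto)
        area = np.pi * (15.0 / 0.7598) ** 2
        ring = 2 * np.pi * (15.0 / 0.7598) * 2  # generous boundary ring
        assert abs((m > 0).sum() - area) <= ring

    def test_grid_aligned_rectangle_uniform(self):
        proto = ExperimentProtocol(
            n_side=64, padding=16,
            bleach_region=BleachRegion(shape="rectangle", center=(31.5, 31.5),
                                       half_size=(8.0, 6.0)))
        m = make_roi_weights(proto)
        interior = m[m > 0]
        assert interior.max() == pytest.approx(interior.min(), rel=1e-12)


class TestDiffuse:
    def test_dt_zero_is_identity(self, rng):
        f = rng.random((64, 64))
        assert np.max(np.abs(diffuse(f, 1.0, 0.0) - f)) < 1e-12

    def test_uniform_field_unchanged(self):
        f = np.full((64, 64), 0.7)
        out = diffuse(f, 2.5, 10.0)
        assert np.max(np.abs(out - 0.7)) < 1e-12

    def test_gaussian_dip_matches_heat_kernel(self):
        """Spectral diffusion of a Gaussian dip reproduces the closed-form
        variance growth s^2 -> s^2 + 2 D dt of the heat kernel."""
        n = 256
        x = np.arange(n)
        cx = (n - 1) / 2
        s2 = 100.0           # s = 10 px
        d_px, dt = 25.0, 2.0  # 2 D dt = 100 -> s'^2 = 200, s' = 14.1 px << n/8
        X, Y = np.meshgrid(x, x)
        r2 = (X - cx) ** 2 + (Y - cx) ** 2
        f = 1.0 - 0.5 * np.exp(-r2 / (2 * s2))
        out = diffuse(f, np.log10(d_px), dt)
        s2_new = s2 + 2 * d_px * dt
        expected = 1.0 - 0.5 * (s2 / s2_new) * np.exp(-r2 / (2 * s2_new))
        assert np.max(np.abs(out - expected) / expected) < 1e-6

    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.floats(min_value=-2, max_value=3),
           st.floats(min_value=0.01, max_value=50.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_mass_conservation(self, seed, d_star, dt):
        f = np.random.default_rng(seed).random((48, 48))
        assert abs(diffuse(f, d_star, dt).mean() - f.mean()) < 1e-12

    def test_rotational_symmetry(self, proto64):
        """Centered circular bleach: simulated fields commute with 90-degree
        rotation."""
        params = SampleParams(d_star=1.2, c0=0.8, alpha=0.6)
        seq = simulate_sequence(proto64, params)
        frame = seq.postbleach[5]
        assert np.max(np.abs(frame - np.rot90(frame))) < 1e-10

    def test_linearity_in_c0(self, proto64):
        k = 0.5
        base = simulate_recovery_curve(
            proto64, SampleParams(d_star=1.5, c0=1.0, alpha=0.7))
        scaled = simulate_recovery_curve(
            proto64, SampleParams(d_star=1.5, c0=k, alpha=0.7))
        np.testing.assert_allclose(scaled.values, k * base.values, rtol=1e-12)


class TestSimulateSequence:
    def test_no_bleach_all_frames_constant(self, proto64):
        seq = simulate_sequence(proto64, SampleParams(d_star=1.0, c0=0.8,
                                                      alpha=1.0))
        assert np.max(np.abs(seq.prebleach - 0.8)) < 1e-12
        assert np.max(np.abs(seq.postbleach - 0.8)) < 1e-12

    def test_zero_diffusion_interior_plateau(self, proto64):
        """With D = 0 and four bleach frames, a deep-interior pixel sits at
        alpha^4 * c0 in every postbleach frame."""
        params = SampleParams(d_star=-30.0, c0=1.0, alpha=0.9)
        seq = simulate_sequence(proto64, params)
        c = 31  # near region center; radius 10 px so well interior
        vals = seq.postbleach[:, c, c]
        np.testing.assert_allclose(vals, 0.9**4, atol=1e-12)

    def test_curve_length_matches_protocol(self, proto128):
        curve = simulate_recovery_curve(
            proto128, SampleParams(d_star=1.9, c0=0.75, alpha=0.7))
        assert len(curve) == 110
        assert len(curve.times) == 110
        assert np.all(np.diff(curve.times) > 0)

    def test_postbleach_strictly_increasing(self, proto64):
        curve = simulate_recovery_curve(
            proto64, SampleParams(d_star=1.0, c0=0.75, alpha=0.7))
        post = curve.values[proto64.n_prebleach:]
        assert np.all(np.diff(post) > 0)

    def test_curve_is_composition(self, proto64):
        params = SampleParams(d_star=1.3, c0=0.9, alpha=0.55)
        seq = simulate_sequence(proto64, params)
        m = make_roi_weights(proto64)
        direct = simulate_recovery_curve(proto64, params)
        composed = extract_recovery_curve(seq, m)
        assert np.array_equal(direct.values, composed.values)

    def test_long_time_limit_is_padded_mean(self):
        """Mass conservation on the periodic padded domain: the recovery
        plateau equals the padded-grid mean after the last bleach event."""
        proto = ExperimentProtocol(
            n_side=32, padding=16, n_prebleach=2, n_bleach=2, n_postbleach=60,
            bleach_region=BleachRegion(shape="circle", radius=6.0))
        params = SampleParams(d_star=2.2, c0=0.8, alpha=0.5)
        # independent composition of the public primitives
        mask = make_bleach_mask(proto, params.alpha)
        c = np.full((proto.grid_side,) * 2, params.c0)
        for _ in range(proto.n_bleach):
            c = diffuse(c * mask, params.d_star, proto.dt)
        curve = simulate_recovery_curve(proto, params)
        assert curve.values[-1] == pytest.approx(c.mean(), abs=1e-6)

    def test_determinism(self, proto64):
        params = SampleParams(d_star=0.9, c0=0.6, alpha=0.8)
        a = simulate_recovery_curve(proto64, params)
        b = simulate_recovery_curve(proto64, params)
        assert np.array_equal(a.values, b.values)


class TestSpectralShortcut:
    def test_matches_frame_simulation(self, proto64):
        """The Fourier-space curve evaluator agrees with the frame-by-frame
        simulation essentially to round-off."""
        for d_star, c0, alpha in [(0.5, 0.6, 0.5), (1.9, 0.75, 0.7),
                                  (3.0, 1.0, 0.95)]:
            slow = simulate_recovery_curve(
                proto64, SampleParams(d_star=d_star, c0=c0, alpha=alpha))
            fast = model_recovery_curve(proto64, d_star, c0, alpha)
            assert np.max(np.abs(slow.values - fast)) < 1e-10
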