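import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deastrain import (
    DeviceConfig,
    StrainField,
    VoltageArray,
    VoltageStrainCurve,
    downsample_field,
    engineering_to_true_strain,
    reachable_strain_range,
    simulate,
    strain_from_voltage,
    voltage_from_strain,
)


class TestEngineeringToTrueStrain:
    def test_prestretch_value(self):
        # 100% biaxial engineering prestretch -> 69.31% true strain
        assert round(100 * engineering_to_true_strain(1.0), 2) == 69.31

    def test_zero(self):
        assert engineering_to_true_strain(0.0) == 0.0

    def test_half(self):
        # independent closed form: ln(1.5)
        assert engineering_to_true_strain(0.5) == pytest.approx(math.log(1.5), abs=1e-12)
        assert engineering_to_true_strain(0.5) == pytest.approx(0.4055, abs=5e-5)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            engineering_to_true_strain(-1.0)

    @given(st.floats(min_value=-0.99, max_value=10.0))
    @settings(max_examples=50, deadline=None)
    def test_matches_log1p(self, e):
        assert engineering_to_true_strain(e) == pytest.approx(math.log(1.0 + e))


class TestCalibrationCurve:
    def test_strain_at_zero_kv(self, curve):
        # independent high-precision evaluation of the dual-Gaussian formula
        expected = 7.756e15 * math.exp(-((0 - 24.1) / 2.964) ** 2) + 47.69 * math.exp(
            -((0 - 10.18) / 4.401) ** 2
        )
        assert expected == pytest.approx(0.226, abs=5e-4)
        assert strain_from_voltage(0.0, curve) == pytest.approx(expected, rel=1e-12)

    def test_strain_at_max_kv(self, curve):
        expected = 7.756e15 * math.exp(-((7.1 - 24.1) / 2.964) ** 2) + 47.69 * math.exp(
            -((7.1 - 10.18) / 4.401) ** 2
        )
        assert expected == pytest.approx(69.32, abs=0.01)
        assert strain_from_voltage(7.1, curve) == pytest.approx(expected, rel=1e-12)

    def test_monotone_pair(self, curve):
        assert strain_from_voltage(5.0, curve) < strain_from_voltage(6.0, curve)

    def test_strictly_increasing_on_range(self, curve):
        v = np.linspace(0.0, 7.1, 10_000)
        eps = np.asarray(curve(v))
        assert np.all(np.diff(eps) > 0)

    def test_range_error(self, curve):
        with pytest.raises(ValueError):
            strain_from_voltage(7.2, curve)
        with pytest.raises(ValueError):
            strain_from_voltage(-0.1, curve)


class TestVoltageFromStrain:
    def test_round_trip(self, curve, config):
        assert voltage_from_strain(
            strain_from_voltage(3.5, curve), curve, config
        ) == pytest.approx(3.5, abs=1e-6)

    def test_boundary_round_trip(self, curve, config):
        eps_max = strain_from_voltage(7.1, curve)
        assert voltage_from_strain(eps_max, curve, config) == pytest.approx(7.1, abs=1e-6)

    def test_round_trip_random(self, curve, config, rng):
        v = rng.uniform(0.0, 7.1, 100)
        back = voltage_from_strain(np.asarray(curve(v)), curve, config)
        assert np.allclose(back, v, atol=1e-6)

    @pytest.mark.parametrize("eps", [1.0, 10.0, 35.0, 60.0])
    def test_against_grid_search(self, curve, config, eps):
        # brute-force oracle: densest-grid argmin of |strain(V) - eps|
        v_grid = np.linspace(0.0, 7.1, 1_000_001)
        oracle = v_grid[np.argmin(np.abs(np.asarray(curve(v_grid)) - eps))]
        assert voltage_from_strain(eps, curve, config) == pytest.approx(oracle, abs=1e-3)

    def test_unreachable_reports_interval(self, curve, config):
        with pytest.raises(ValueError, match="reachable range"):
            voltage_from_strain(100.0, curve, config)
        with pytest.raises(ValueError, match="reachable range"):
            voltage_from_strain(0.0, curve, config)


class TestSimulate:
    def test_constant_input_plateau(self, config, curve):
        va = VoltageArray(np.full((9, 9), 4.0))
        fx, fy = simulate(va, config, curve, resolution="lr")
        target = strain_from_voltage(4.0, curve)
        interior = fx.values[15:45, 15:45]
        assert np.allclose(interior, target, rtol=1e-9)
        assert np.allclose(fy.values[15:45, 15:45], target, rtol=1e-9)

    def test_transpose_symmetry(self, config, curve, rng):
        v = rng.uniform(0.0, 7.1, (9, 9))
        fx, fy = simulate(VoltageArray(v), config, curve, resolution="hr")
        fxt, fyt = simulate(VoltageArray(v.T), config, curve, resolution="hr")
        assert np.allclose(fxt.values, fy.values.T)
        assert np.allclose(fyt.values, fx.values.T)

    def test_deterministic(self, config, curve, rng):
        v = rng.uniform(0.0, 7.1, (9, 9))
        a, _ = simulate(VoltageArray(v), config, curve)
        b, _ = simulate(VoltageArray(v), config, curve)
        assert np.array_equal(a.values, b.values)

    def test_order_preservation(self, config, curve, rng):
        hi = rng.uniform(0.0, 7.1, (9, 9))
        lo = np.clip(hi - rng.uniform(0.0, 2.0, (9, 9)), 0.0, 7.1)
        fh, gh = simulate(VoltageArray(hi), config, curve, resolution="hr")
        fl, gl = simulate(VoltageArray(lo), config, curve, resolution="hr")
        assert np.all(fh.values - fl.values >= -1e-9)
        assert np.all(gh.values - gl.values >= -1e-9)

    def test_fields_finite_nonnegative(self, config, curve, rng):
        v = rng.uniform(0.0, 7.1, (9, 9))
        fx, fy = simulate(VoltageArray(v), config, curve)
        for fld in (fx, fy):
            assert np.all(np.isfinite(fld.values))
            assert np.all(fld.values >= 0.0)

    def test_single_pixel_monotone_decay(self, config, curve):
        v = np.zeros((9, 9))
        v[4, 4] = 7.1
        fx, _ = simulate(VoltageArray(v), config, curve, resolution="hr")
        col = fx.values[:, 240]  # through the energized pixel, along the blur axis
        peak = np.argmax(col)
        assert abs(peak - 240) < 30
        up, down = col[: peak + 1], col[peak:]
        assert np.all(np.diff(up) >= -1e-9)
        assert np.all(np.diff(down) <= 1e-9)

    def test_lr_matches_downsampled_hr(self, config, curve, rng):
        # stated interpolation tolerance: 6% max / 0.7% mean of display range
        span = config.strain_display_max - config.strain_display_min
        for _ in range(3):
            va = VoltageArray(rng.uniform(0.0, 7.1, (9, 9)))
            fhr, _ = simulate(va, config, curve, resolution="hr")
            flr, _ = simulate(va, config, curve, resolution="lr")
            diff = np.abs(downsample_field(fhr, config.scale_factor).values - flr.values)
            assert diff.max() / span < 0.06
            assert diff.mean() / span < 0.007

    def test_blur_matches_brute_force_convolution(self, config):
        # the coupling blur is a normalized Gaussian: check scipy's output
        # against a dense brute-force weighted sum on an impulse row
        from scipy.ndimage import gaussian_filter1d

        impulse = np.zeros(101)
        impulse[50] = 1.0
        sigma = config.coupling_sigma_perpendicular * (480 / config.grid_n)
        out = gaussian_filter1d(impulse, sigma, mode="nearest")
        radius = int(4.0 * sigma + 0.5)
        t = np.arange(-radius, radius + 1)
        w = np.exp(-(t**2) / (2 * sigma**2))
        w /= w.sum()
        brute = np.array(
            [sum(w[j + radius] * impulse[min(max(i + j, 0), 100)] for j in t) for i in range(101)]
        )
        assert np.allclose(out, brute, atol=1e-6)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)


class TestDomainTypes:
    def test_voltage_array_validation(self, config):
        with pytest.raises(ValueError):
            VoltageArray(np.zeros((9, 8)))
        with pytest.raises(ValueError):
            VoltageArray(np.full((9, 9), 8.0)).validate(config)
        with pytest.raises(ValueError):
            VoltageArray(np.full((8, 8), 1.0)).validate(config)

    def test_strain_field_invariants(self):
        with pytest.raises(ValueError):
            StrainField("Z", np.zeros((4, 4)))
        with pytest.raises(ValueError):
            StrainField("X", np.full((4, 4), np.nan))
        with pytest.raises(ValueError):
            StrainField("X", np.zeros((4, 5)))

    def test_display_mapping_linear(self, config):
        fld = StrainField("X", np.array([[0.0, 35.0], [70.0, 140.0]]))
        gray = fld.to_gray(config)
        assert gray[0, 0] == 0.0
        assert gray[0, 1] == pytest.approx(0.5)
        assert gray[1, 0] == 1.0
        assert gray[1, 1] == 1.0  # clipped

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            DeviceConfig(voltage_min=5.0, voltage_max=2.0)
        with pytest.raises(ValueError):
            DeviceConfig(boundary_margin=0.6)
        with pytest.raises(ValueError):
            DeviceConfig(hr_size=470)
        assert DeviceConfig().hr_size == 8 * DeviceConfig().lr_size

    def test_reachable_range(self, curve, config):
        lo, hi = reachable_strain_range(curve, config)
        assert lo == pytest.approx(0.226, abs=5e-4)
        assert hi == pytest.approx(69.32, abs=0.01)
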