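import math

import numpy as np
import pytest
from scipy import stats

from deastrain import (
    DeviceConfig,
    SamplingScheme,
    VoltageArray,
    VoltageStrainCurve,
    build_dataset,
    extract_center_strains,
    fit_dual_gaussian,
    reachable_strain_range,
    sample_voltage_arrays,
    simulate,
    strain_distribution_metrics,
)


class TestSampleVoltageArrays:
    def test_uniform_strain_ks(self, config, curve):
        arrs = sample_voltage_arrays(1000, SamplingScheme("uniform_strain", seed=1), curve, config)
        lo, hi = reachable_strain_range(curve, config)
        strains = np.concatenate([np.asarray(curve(a.values)).ravel() for a in arrs[:200]])
        stat = stats.kstest(strains, stats.uniform(loc=lo, scale=hi - lo).cdf)
        assert stat.pvalue > 0.01

    def test_uniform_voltage_ks(self, config, curve):
        arrs = sample_voltage_arrays(200, SamplingScheme("uniform_voltage", seed=1), curve, config)
        volts = np.concatenate([a.values.ravel() for a in arrs])
        stat = stats.kstest(volts, stats.uniform(loc=0.0, scale=7.1).cdf)
        assert stat.pvalue > 0.01

    def test_determinism(self, config, curve):
        a = sample_voltage_arrays(5, SamplingScheme(seed=3), curve, config)
        b = sample_voltage_arrays(5, SamplingScheme(seed=3), curve, config)
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)

    def test_all_in_range(self, config, curve):
        for kind in ("uniform_voltage", "uniform_strain"):
            for a in sample_voltage_arrays(20, SamplingScheme(kind, seed=2), curve, config):
                a.validate(config)

    def test_bad_bounds(self, config, curve):
        with pytest.raises(ValueError):
            sample_voltage_arrays(
                2, SamplingScheme("uniform_strain", seed=0, strain_lo=0.0, strain_hi=500.0),
                curve, config,
            )
        with pytest.raises(ValueError):
            sample_voltage_arrays(0, SamplingScheme(seed=0), curve, config)


class TestExtractCenterStrains:
    def test_constant_field(self, config, curve):
        fx, _ = simulate(VoltageArray(np.full((9, 9), 5.0)), config, curve, "hr")
        vals = extract_center_strains(fx, config)
        assert vals.shape == (81,)
        assert np.allclose(vals, curve(5.0), rtol=1e-6)

    def test_recovers_commanded_without_coupling(self, curve, rng):
        from dataclasses import replace

        cfg = replace(DeviceConfig(), coupling_sigma_perpendicular=0.0, boundary_margin=0.0)
        v = rng.uniform(0.0, 7.1, (9, 9))
        fx, _ = simulate(VoltageArray(v), cfg, curve, "hr")
        commanded = np.asarray(curve(v)).ravel()
        got = extract_center_strains(fx, cfg)
        # bilinear sampling at the interpolation kinks leaves a residual of
        # ~0.6% of the strain range at 480 px
        assert np.abs(got - commanded).max() < 0.8

    def test_row_major_order(self, config, curve):
        v = np.zeros((9, 9))
        v[0, 8] = 7.1  # top-right pixel -> index 8 in row-major order
        fx, _ = simulate(VoltageArray(v), config, curve, "hr")
        vals = extract_center_strains(fx, config)
        assert np.argmax(vals) == 8


class TestStrainDistributionMetrics:
    def test_uniform_limit(self):
        vals = np.repeat(np.arange(7) + 0.5, 10)  # 10 counts per bin on [0, 7]
        std, ent = strain_distribution_metrics(vals, n_bins=7, strain_lo=0.0, strain_hi=7.0)
        assert std == pytest.approx(0.0, abs=1e-12)
        assert ent == pytest.approx(math.log(7), abs=1e-12)

    def test_single_bin_mass(self):
        vals = np.full(100, 0.5)
        std, ent = strain_distribution_metrics(vals, n_bins=7, strain_lo=0.0, strain_hi=7.0)
        # hand evaluation: p = (1,0,...,0); sqrt(((1-1/7)^2 + 6*(1/7)^2)/6)
        assert std == pytest.approx(math.sqrt((36 / 49 + 6 / 49) / 6), abs=1e-12)
        assert std == pytest.approx(0.3780, abs=1e-4)
        assert ent == 0.0

    def test_pooled_simulated_fields(self, config, curve):
        lo, hi = reachable_strain_range(curve, config)
        arrs = sample_voltage_arrays(10, SamplingScheme(seed=5), curve, config)
        pooled = np.concatenate(
            [extract_center_strains(simulate(a, config, curve, "hr")[0], config) for a in arrs]
        )
        std, ent = strain_distribution_metrics(pooled, 7, lo, hi)
        assert std <= 0.05
        assert ent >= 1.85

    def test_order_invariance(self, rng):
        vals = rng.uniform(0, 1, 500)
        shuffled = rng.permutation(vals)
        assert strain_distribution_metrics(vals, 7, 0, 1) == strain_distribution_metrics(
            shuffled, 7, 0, 1
        )

    def test_degenerate_range_warns(self):
        with pytest.warns(UserWarning):
            std, ent = strain_distribution_metrics(np.full(10, 3.0), n_bins=7)
        assert ent == 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            strain_distribution_metrics([1.0], n_bins=7)
        with pytest.raises(ValueError):
            strain_distribution_metrics([1.0, 2.0], n_bins=1)

    @pytest.mark.parametrize("n_bins", [3, 5, 7])
    def test_uniform_strain_beats_uniform_voltage(self, config, curve, n_bins):
        lo, hi = reachable_strain_range(curve, config)
        pooled = {}
        for kind in ("uniform_strain", "uniform_voltage"):
            arrs = sample_voltage_arrays(10, SamplingScheme(kind, seed=11), curve, config)
            pooled[kind] = np.concatenate(
                [
                    extract_center_strains(simulate(a, config, curve, "hr")[0], config)
                    for a in arrs
                ]
            )
        std_s, ent_s = strain_distribution_metrics(pooled["uniform_strain"], n_bins, lo, hi)
        std_v, ent_v = strain_distribution_metrics(pooled["uniform_voltage"], n_bins, lo, hi)
        assert std_s < std_v
        assert ent_s > ent_v


class TestFitDualGaussian:
    def test_noiseless_recovery(self, curve):
        v = np.linspace(0.0, 7.1, 50)
        eps = np.asarray(curve(v))
        fitted, r2 = fit_dual_gaussian(v, eps)
        assert r2 >= 0.9998
        dense = np.linspace(0.0, 7.1, 500)
        rel = np.abs(np.asarray(fitted(dense)) - np.asarray(curve(dense))) / np.asarray(
            curve(dense)
        )
        assert rel.max() < 1e-3

    def test_constant_data_no_crash(self):
        with pytest.warns(UserWarning):
            _, r2 = fit_dual_gaussian(np.linspace(0, 7, 10), np.full(10, 5.0))
        assert math.isnan(r2)

    def test_noisy_recovery(self, curve):
        rng = np.random.default_rng(42)
        v = rng.uniform(0.0, 7.1, 200)
        eps = np.asarray(curve(v)) * (1.0 + 0.05 * rng.standard_normal(200))
        fitted, r2 = fit_dual_gaussian(v, eps)
        dense = np.linspace(0.2, 7.1, 200)
        rel = np.abs(np.asarray(fitted(dense)) - np.asarray(curve(dense))) / np.asarray(
            curve(dense)
        )
        assert rel.max() < 0.12

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_dual_gaussian([1, 2, 3], [1, 2, 3])


class TestBuildDataset:
    def test_bookkeeping(self, config, curve, tmp_path):
        ds = build_dataset(20, 5, SamplingScheme(seed=1), config, curve, out_dir=tmp_path)
        assert ds.n == 25
        assert ds.voltages.shape == (25, 9, 9)
        assert ds.lr_x.shape == (25, 60, 60)
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "voltages.csv").exists()
        pngs = list((tmp_path / "images").glob("*.png"))
        assert len(pngs) == 50  # one X + one Y LR image per sample
        assert ds.manifest()["n_train"] == 20
        assert ds.manifest()["n_test"] == 5

    def test_manifest_reproducible(self, config, curve):
        a = build_dataset(5, 2, SamplingScheme(seed=9), config, curve)
        b = build_dataset(5, 2, SamplingScheme(seed=9), config, curve)
        assert a.manifest()["content_sha256"] == b.manifest()["content_sha256"]

    def test_hr_field_on_demand(self, small_dataset, config):
        fld = small_dataset.hr_field(0, "X")
        assert fld.size == config.hr_size

    def test_counts_validated(self, config, curve):
        with pytest.raises(ValueError):
            build_dataset(0, 5, SamplingScheme(seed=0), config, curve)
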