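"""Dosimetry chain: calibration, density conversion, kernel convolution,
single-time-point integration, bias ratio, organ dose statistics."""

import math

import numpy as np
import pytest

from lutidose import (
    CalibrationConfig,
    DensityTable,
    TimingParams,
    VolumeGrid,
    convolve_dose_rate,
    counts_to_activity,
    dose_stats,
    hanscheid_integrate,
    hu_to_density,
    make_test_kernel,
    underestimation_ratio,
)
from lutidose.errors import KernelError, QuantityError

from conftest import mask_from_array


def _grid(values, spacing=(1.0, 1.0, 1.0), quantity="cps"):
    return VolumeGrid(np.asarray(values, dtype=float), spacing, quantity)


class TestCountsToActivity:
    @pytest.mark.parametrize("cps,ccf,mbq", [(9.64, 9.64, 1.0), (19.84, 9.92, 2.0),
                                             (0.0, 9.64, 0.0)])
    def test_conversion(self, cps, ccf, mbq):
        counts = _grid(np.full((2, 2, 2), cps))
        out = counts_to_activity(counts, CalibrationConfig(ccf=ccf))
        assert out.quantity == "MBq"
        np.testing.assert_allclose(out.values, mbq)

    def test_negative_counts_rejected(self):
        counts = _grid(np.full((2, 2, 2), -1.0))
        with pytest.raises(ValueError):
            counts_to_activity(counts, CalibrationConfig())

    def test_wrong_quantity_rejected(self):
        dose = _grid(np.ones((2, 2, 2)), quantity="Gy")
        with pytest.raises(QuantityError):
            counts_to_activity(dose, CalibrationConfig())


class TestDensity:
    def test_water_anchor(self):
        ct = _grid(np.zeros((2, 2, 2)), quantity="HU")
        rho = hu_to_density(ct, DensityTable((-1000, 0), (0.001, 1.0)))
        np.testing.assert_allclose(rho.values, 1.0)
        assert rho.quantity == "g_per_cm3"

    def test_linear_interpolation(self):
        ct = _grid(np.full((1, 1, 1), -500.0), quantity="HU")
        rho = hu_to_density(ct, DensityTable((-1000, 0), (0.001, 1.0)))
        assert rho.values[0, 0, 0] == pytest.approx(0.5005)

    def test_clamped_above_table(self):
        ct = _grid(np.full((1, 1, 1), 5000.0), quantity="HU")
        table = DensityTable((-1000, 0, 1000), (0.001, 1.0, 1.61))
        assert hu_to_density(ct, table).values[0, 0, 0] == pytest.approx(1.61)

    def test_short_table_rejected(self):
        with pytest.raises(ValueError):
            DensityTable((0.0,), (1.0,))

    def test_missing_water_anchor_rejected(self):
        with pytest.raises(ValueError, match="HU 0"):
            DensityTable((-1000, 100), (0.001, 2.0))


class TestConvolution:
    def test_impulse_response_is_kernel(self):
        kernel = make_test_kernel((1, 1, 1), self_fraction=0.6, range_mm=1.0)
        shape = tuple(n + 6 for n in kernel.values.shape)
        act = np.zeros(shape)
        center = tuple(n // 2 for n in shape)
        act[center] = 1.0
        rate = convolve_dose_rate(_grid(act, quantity="MBq"), kernel)
        assert rate.quantity == "Gy_per_s"
        h = tuple(n // 2 for n in kernel.values.shape)
        sub = rate.values[
            center[0] - h[0]: center[0] + h[0] + 1,
            center[1] - h[1]: center[1] + h[1] + 1,
            center[2] - h[2]: center[2] + h[2] + 1,
        ]
        np.testing.assert_allclose(sub, kernel.values, rtol=1e-12)

    def test_uniform_interior_equals_activity_times_kernel_sum(self):
        kernel = make_test_kernel((1, 1, 1), self_fraction=0.7, range_mm=1.0)
        a = 0.37
        act = np.full((15, 15, 15), a)
        rate = convolve_dose_rate(_grid(act, quantity="MBq"), kernel)
        assert rate.values[7, 7, 7] == pytest.approx(a * kernel.total, rel=1e-12)

    def test_zero_activity_zero_rate(self):
        kernel = make_test_kernel((1, 1, 1))
        rate = convolve_dose_rate(_grid(np.zeros((5, 5, 5)), quantity="MBq"), kernel)
        assert not rate.values.any()

    def test_spacing_mismatch_rejected(self):
        kernel = make_test_kernel((2, 2, 2))
        with pytest.raises(KernelError, match="spacing"):
            convolve_dose_rate(_grid(np.ones((5, 5, 5)), quantity="MBq"), kernel)

    def test_refuses_non_activity_input(self):
        kernel = make_test_kernel((1, 1, 1))
        with pytest.raises(QuantityError):
            convolve_dose_rate(_grid(np.ones((5, 5, 5)), quantity="Gy"), kernel)

    def test_energy_bookkeeping_interior_source(self, rng):
        """Zero-padded convolution conserves Σ(rate) = Σ(activity)·Σ(kernel)
        when the activity sits fully interior to the lattice."""
        kernel = make_test_kernel((1, 1, 1), self_fraction=0.6, range_mm=1.5)
        h = kernel.values.shape[0] // 2
        act = np.zeros((25, 25, 25))
        core = slice(h, 25 - h)
        act[core, core, core] = rng.random((25 - 2 * h,) * 3)
        rate = convolve_dose_rate(_grid(act, quantity="MBq"), kernel)
        assert rate.values.sum() == pytest.approx(act.sum() * kernel.total, rel=1e-12)

    def test_density_correction_scales_by_inverse_density(self):
        kernel = make_test_kernel((1, 1, 1), self_fraction=1.0)
        act = _grid(np.ones((3, 3, 3)), quantity="MBq")
        rho = _grid(np.full((3, 3, 3), 2.0), quantity="g_per_cm3")
        corrected = convolve_dose_rate(act, kernel, density=rho)
        plain = convolve_dose_rate(act, kernel)
        np.testing.assert_allclose(corrected.values, plain.values / 2.0)


class TestHanscheid:
    def test_zero_rate_zero_dose(self):
        rate = _grid(np.zeros((2, 2, 2)), quantity="Gy_per_s")
        dose = hanscheid_integrate(rate, TimingParams(t_hours=24.0))
        assert not dose.values.any()
        assert dose.quantity == "Gy"

    def test_closed_form_value(self):
        rate = _grid(np.full((1, 1, 1), 1.0 / 3600.0), quantity="Gy_per_s")  # 1 Gy/h
        dose = hanscheid_integrate(rate, TimingParams(t_hours=24.0))
        assert dose.values[0, 0, 0] == pytest.approx(2 * 24 / math.log(2))

    def test_exact_at_effective_half_life(self):
        """Against a monoexponential ground truth imaged at t = T_eff the
        single-time-point estimate equals the true integral exactly."""
        t_eff = 51.0
        lam = math.log(2) / t_eff  # 1/h
        d0 = 1e-3  # Gy/h at time zero
        t = t_eff
        rate_at_t = d0 * math.exp(-lam * t)  # Gy/h
        true_integral = d0 / lam  # Gy, integral over [0, inf)
        rate = _grid(np.full((1, 1, 1), rate_at_t / 3600.0), quantity="Gy_per_s")
        est = hanscheid_integrate(rate, TimingParams(t_hours=t)).values[0, 0, 0]
        # the estimator also misses the activity accumulated before imaging;
        # at t = T_eff the 2t/ln2 window reproduces the full integral
        assert est == pytest.approx(true_integral, rel=1e-12)

    def test_wrong_quantity_rejected(self):
        with pytest.raises(QuantityError):
            hanscheid_integrate(_grid(np.ones((1, 1, 1)), quantity="Gy"),
                                TimingParams())


class TestBiasRatio:
    def test_identity_at_t_eff(self):
        assert underestimation_ratio(TimingParams(t_hours=51, t_eff_hours=51)) == 1.0

    @pytest.mark.parametrize("t_eff,expected_pct", [(51.0, 31.1), (67.0, 43.3),
                                                    (68.0, 43.9)])
    def test_reported_underestimation(self, t_eff, expected_pct):
        r = underestimation_ratio(TimingParams(t_hours=24.49, t_eff_hours=t_eff))
        assert 100 * (1 - r) == pytest.approx(expected_pct, abs=0.2)

    def test_window_accuracy_bound(self):
        """|1 - r| <= 0.12 over the 75–250% validity window, maximum of r
        near x = 1/ln2."""
        xs = np.linspace(0.75, 2.5, 400)
        rs = np.array([
            underestimation_ratio(TimingParams(t_hours=x, t_eff_hours=1.0))
            for x in xs
        ])
        assert np.abs(1 - rs).max() <= 0.12
        assert xs[np.argmax(rs)] == pytest.approx(1 / math.log(2), abs=0.01)


class TestDoseStats:
    def test_uniform_dose(self):
        dose = _grid(np.full((3, 3, 3), 2.0), quantity="Gy")
        mask = mask_from_array(np.ones((3, 3, 3), bool))
        ds = dose_stats(dose, mask)
        assert (ds.d_mean, ds.d_max, ds.d_min) == (2.0, 2.0, 2.0)

    def test_mixed_values(self):
        values = np.zeros((1, 1, 4))
        values[0, 0, :3] = [1.0, 2.0, 6.0]
        m = np.zeros((1, 1, 4), bool)
        m[0, 0, :3] = True
        ds = dose_stats(_grid(values, quantity="Gy"), mask_from_array(m))
        assert (ds.d_mean, ds.d_max, ds.d_min) == (3.0, 6.0, 1.0)

    def test_volume_product(self):
        spacing = (1.5, 1.37, 1.37)
        m = np.zeros((10, 10, 10), bool)
        m.flat[:1000] = True
        ds = dose_stats(_grid(np.ones((10, 10, 10)), spacing, "Gy"),
                        mask_from_array(m, spacing))
        assert ds.volume_ml == pytest.approx(2.815, abs=1e-2)

    def test_linearity_of_full_chain(self, rng):
        """Scaling activity by k scales every dose statistic by k."""
        from lutidose import compute_dose_map

        kernel = make_test_kernel((2, 2, 2), self_fraction=0.7, range_mm=2.0)
        counts = rng.random((12, 12, 12)) * 5
        m = np.zeros((12, 12, 12), bool)
        m[4:8, 4:8, 4:8] = True
        mask = mask_from_array(m, (2, 2, 2))
        cal, timing = CalibrationConfig(), TimingParams()
        ds1 = dose_stats(
            compute_dose_map(_grid(counts, (2, 2, 2)), cal, kernel, timing), mask)
        ds3 = dose_stats(
            compute_dose_map(_grid(3 * counts, (2, 2, 2)), cal, kernel, timing), mask)
        assert ds3.d_mean == pytest.approx(3 * ds1.d_mean, rel=1e-12)
        assert ds3.d_max == pytest.approx(3 * ds1.d_max, rel=1e-12)
        assert ds3.d_min == pytest.approx(3 * ds1.d_min, rel=1e-12)


class TestTestKernel:
    def test_pure_local_deposition(self):
        kernel = make_test_kernel((1, 1, 1), self_fraction=1.0, total=1e-4)
        assert kernel.values.shape == (1, 1, 1)
        assert kernel.total == pytest.approx(1e-4)

    def test_mass_normalization(self):
        kernel = make_test_kernel((1.5, 1.37, 1.37), self_fraction=0.6,
                                  range_mm=3.0, total=2e-4)
        assert kernel.total == pytest.approx(2e-4, rel=1e-9)
        assert kernel.values[kernel.center_index] == pytest.approx(0.6 * 2e-4)

    def test_shorter_range_concentrates_mass(self):
        near = make_test_kernel((1, 1, 1), self_fraction=0.5, range_mm=1.0)
        far = make_test_kernel((1, 1, 1), self_fraction=0.5, range_mm=2.0)

        def mass_within(kernel, radius_mm):
            h = [n // 2 for n in kernel.values.shape]
            ax = [np.arange(-hh, hh + 1) * s for hh, s in zip(h, kernel.spacing)]
            r = np.sqrt(ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                        + ax[2][None, None, :] ** 2)
            return kernel.values[r <= radius_mm].sum() / kernel.total

        assert mass_within(near, 2.0) > mass_within(far, 2.0)
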