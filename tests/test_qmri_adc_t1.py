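"""ADC and T1 fitting, and the DWI quality filters."""

import numpy as np
import pytest

from tumorhab.qmri import apply_dwi_slice_scan_filters, fit_adc, fit_t1
from tumorhab.synth import simulate_dwi, simulate_ir

B = (150.0, 500.0, 800.0)


def grid_search_adc_oracle(signal, b_values, grid):
    """Dense-grid least-squares oracle on the log-linear objective."""
    logs = np.log(signal)
    best, best_sse = None, np.inf
    for adc in grid:
        # closed-form intercept for fixed slope
        resid = logs + adc * np.asarray(b_values)
        resid = resid - resid.mean()
        sse = (resid ** 2).sum()
        if sse < best_sse:
            best, best_sse = adc, sse
    return best


class TestADC:
    def test_noiseless_exact_recovery(self):
        adc = np.full((6, 6, 2), 7e-4)
        series = simulate_dwi(adc, B, noise_sd=0.0)
        res = fit_adc(series, B)
        np.testing.assert_allclose(res.adc_map, 7e-4, rtol=1e-10)
        assert not res.removed_mask.any()

    def test_non_monotone_voxel_removed(self):
        series = np.array([[[1000.0, 600.0, 600.0]]])  # S(500) == S(800)
        res = fit_adc(series, B)
        assert res.removed_mask[0, 0]
        assert not res.valid_mask[0, 0]

    def test_noisy_fit_matches_grid_search_oracle(self, rng):
        adc_true = rng.uniform(4e-4, 1.5e-3, size=(1000,))
        series = simulate_dwi(adc_true, B, s0=1000.0, noise_sd=10.0, seed=2)
        res = fit_adc(series, B)
        fitted = res.adc_map[res.valid_mask]
        grid = np.linspace(1e-4, 3e-3, 8000)
        oracle = np.array([grid_search_adc_oracle(s, B, grid)
                           for s in series[res.valid_mask][:50]])
        err_fit = np.abs(fitted[:50] - adc_true[res.valid_mask][:50])
        err_oracle = np.abs(oracle - adc_true[res.valid_mask][:50])
        assert np.median(err_fit) <= np.median(err_oracle) * 1.01

    def test_all_removed_returns_empty_map(self):
        series = np.tile([500.0, 600.0, 700.0], (2, 2, 1, 1)).reshape(2, 2, 1, 3)
        res = fit_adc(series, B)
        assert res.removed_mask.all()
        assert not res.valid_mask.any()


class TestFilters:
    def _mask(self, shape, removed_frac_by_slice):
        roi = np.ones(shape, dtype=bool)
        removed = np.zeros(shape, dtype=bool)
        per_slice = shape[0] * shape[1]
        for s, frac in enumerate(removed_frac_by_slice):
            k = int(round(frac * per_slice))
            removed.reshape(-1, shape[2])[:k, s] = True
        return removed, roi

    def test_strict_20_percent_boundary(self):
        removed, roi = self._mask((10, 10, 2), [0.21, 0.20])
        rep = apply_dwi_slice_scan_filters(removed, roi)
        assert rep.excluded_slices == (0,)  # 21% excluded, exactly 20% retained

    def test_strict_half_scan_boundary(self):
        # 8 of 15 slices excluded -> invalid; 7 of 14 -> valid (not > half)
        removed, roi = self._mask((10, 10, 15), [0.5] * 8 + [0.0] * 7)
        assert not apply_dwi_slice_scan_filters(removed, roi).scan_valid
        removed, roi = self._mask((10, 10, 14), [0.5] * 7 + [0.0] * 7)
        assert apply_dwi_slice_scan_filters(removed, roi).scan_valid

    def test_empty_removal_keeps_everything(self):
        removed, roi = self._mask((6, 6, 4), [0.0] * 4)
        rep = apply_dwi_slice_scan_filters(removed, roi)
        assert rep.excluded_slices == ()
        assert rep.scan_valid
        assert rep.fraction_removed == 0.0

    def test_matches_brute_force_predicate_on_random_masks(self, rng):
        for _ in range(20):
            roi = rng.random((8, 8, 6)) < 0.7
            removed = roi & (rng.random((8, 8, 6)) < 0.3)
            rep = apply_dwi_slice_scan_filters(removed, roi)
            # brute-force re-derivation
            excl = []
            for s in range(6):
                n = roi[:, :, s].sum()
                if n and removed[:, :, s].sum() / n > 0.20:
                    excl.append(s)
            tumor_slices = sum(roi[:, :, s].any() for s in range(6))
            assert tuple(excl) == rep.excluded_slices
            assert rep.scan_valid == (len(excl) / tumor_slices <= 0.5)


class TestT1:
    def test_noiseless_recovery(self):
        series = simulate_ir(np.full((4, 4), 2.0), tr_ms=12000.0, noise_sd=0.0)
        t1, s0, valid = fit_t1(series, tr_ms=12000.0)
        assert valid.all()
        np.testing.assert_allclose(t1, 2.0, rtol=1e-4)
        np.testing.assert_allclose(s0, 1000.0, rtol=1e-3)

    def test_long_tr_limit_matches_two_parameter_model(self):
        tis = (250.0, 500.0, 1000.0, 2000.0, 4000.0, 7000.0, 10000.0)
        ti_s = np.asarray(tis) / 1000.0
        two_param = 1000.0 * np.abs(1.0 - 2.0 * np.exp(-ti_s / 1.5))
        t1, s0, valid = fit_t1(two_param.reshape(1, 1, -1), tis, tr_ms=1e6)
        assert valid.all()
        assert t1[0, 0] == pytest.approx(1.5, rel=1e-3)

    def test_noisy_fit_close_to_2d_grid_oracle(self, rng):
        t1_true = rng.uniform(1.0, 3.0, size=(60,))
        series = simulate_ir(t1_true, noise_sd=20.0, seed=3)
        t1_fit, _, valid = fit_t1(series)
        # dense 2-D grid-search oracle on (T1, S0)
        tis = np.asarray((250.0, 500.0, 1000.0, 2000.0, 4000.0, 7000.0,
                          10000.0)) / 1000.0
        t1g = np.linspace(0.5, 4.0, 1200)
        g = np.abs(1 - 2 * np.exp(-tis[None, :] / t1g[:, None])
                   + np.exp(-12.0 / t1g)[:, None])
        for i in range(10):
            y = series[i]
            s0g = np.clip(g @ y, 0, None) / (g * g).sum(axis=1)
            sse = ((y[None, :] - s0g[:, None] * g) ** 2).sum(axis=1)
            oracle = t1g[np.argmin(sse)]
            assert t1_fit[i] == pytest.approx(oracle, rel=0.01)

    def test_flat_series_flagged_invalid(self):
        series = np.zeros((2, 2, 7))
        _, _, valid = fit_t1(series)
        assert not valid.any()

    def test_too_few_tis_rejected(self):
        with pytest.raises(ValueError):
            fit_t1(np.ones((2, 2, 2)), inversion_times_ms=(250.0, 500.0))
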