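"""Spatiotemporal statistics: detrend, EOF, PSD, lowess, variance, anomalies."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from thetaprime import spatiotemporal as st


def _grid_field(values, start="2000-01-01", freq="8D", lat=None, lon=None):
    nt, ny, nx = values.shape
    return xr.DataArray(
        values, dims=("time", "lat", "lon"),
        coords={"time": pd.date_range(start, periods=nt, freq=freq),
                "lat": lat if lat is not None else np.arange(ny, dtype=float),
                "lon": lon if lon is not None else np.arange(nx, dtype=float)})


class TestDetrendAndTrend:
    def test_constant_series(self):
        field = _grid_field(np.full((50, 2, 3), 5.0))
        det, slope = st.detrend_linear(field)
        np.testing.assert_allclose(det.values, 0.0, atol=1e-12)
        np.testing.assert_allclose(slope.values, 0.0, atol=1e-12)

    def test_pure_line_removed_exactly(self):
        nt = 100
        t = np.arange(nt) * 8 / 365.25
        vals = 2.0 + 0.7 * t
        field = _grid_field(np.tile(vals[:, None, None], (1, 2, 2)))
        det, slope = st.detrend_linear(field)
        np.testing.assert_allclose(slope.values, 0.7, rtol=1e-10)
        np.testing.assert_allclose(det.values, 0.0, atol=1e-10)

    def test_line_plus_sine_slope_recovered(self, rng):
        nt = int(20 * 365.25 / 8)  # 20 years of 8-day composites
        t = np.arange(nt) * 8 / 365.25
        vals = 1.0 + 0.05 * t + 0.3 * np.sin(2 * np.pi * t) + rng.normal(0, 0.05, nt)
        field = _grid_field(vals[:, None, None])
        _, slope = st.detrend_linear(field)
        assert slope.values[0, 0] == pytest.approx(0.05, abs=0.01)

    def test_all_missing_pixel_masked(self):
        vals = np.random.default_rng(0).normal(size=(30, 2, 2))
        vals[:, 0, 0] = np.nan
        det, slope = st.detrend_linear(_grid_field(vals))
        assert np.isnan(slope.values[0, 0])
        assert np.isnan(det.values[:, 0, 0]).all()

    def test_pixel_trend_summaries(self):
        nt = 60
        t = np.arange(nt) * 8 / 365.25
        vals = np.zeros((nt, 1, 2))
        vals[:, 0, 0] = 1.0 + 0.02 * t
        vals[:, 0, 1] = 1.0 - 0.02 * t
        res = st.pixel_trend(_grid_field(vals))
        np.testing.assert_allclose(res.slope.values, [[0.02, -0.02]], rtol=1e-8)
        assert res.positive_area_fraction == pytest.approx(0.5)
        assert res.median_slope == pytest.approx(0.0, abs=1e-10)


class TestEOF:
    def test_rank_one_field_recovered(self, rng):
        """A single planted pattern × time series dominates mode 1."""
        nt, ny, nx = 80, 6, 8
        pattern = rng.normal(size=(ny, nx))
        series = np.sin(2 * np.pi * np.arange(nt) / 12.0)
        vals = series[:, None, None] * pattern[None] + rng.normal(0, 1e-3, (nt, ny, nx))
        res = st.eof_decompose(_grid_field(vals), n_modes=4)
        assert res.variance_fraction[0] > 0.99
        r = np.corrcoef(res.pcs.sel(mode=1).values, series)[0, 1]
        assert abs(r) > 0.99

    def test_orthogonality_and_reconstruction(self, rng):
        vals = rng.normal(size=(40, 5, 6))
        field = _grid_field(vals)
        res = st.eof_decompose(field)
        pcs = res.pcs.values
        gram = pcs @ pcs.T
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)
        recon = res.reconstruct() + field.mean("time")
        xr.testing.assert_allclose(recon.transpose(*field.dims), field, atol=1e-10)

    def test_variance_fractions_sum_to_one(self, rng):
        res = st.eof_decompose(_grid_field(rng.normal(size=(30, 4, 5))))
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)

    def test_sign_convention(self, rng):
        res = st.eof_decompose(_grid_field(rng.normal(size=(30, 4, 5))))
        for m in res.modes["mode"].values:
            loadings = res.modes.sel(mode=m).values.ravel()
            assert loadings[np.nanargmax(np.abs(loadings))] > 0

    def test_gappy_pixels_excluded_listwise(self, rng):
        vals = rng.normal(size=(40, 4, 4))
        vals[:20, 0, 0] = np.nan  # 50% missing > 20% threshold
        res = st.eof_decompose(_grid_field(vals))
        assert np.isnan(res.modes.values[:, 0, 0]).all()
        assert np.isfinite(res.modes.values[:, 1, 1]).all()

    def test_matches_covariance_eigendecomposition_oracle(self, rng):
        """Independent route: eigenvalues of the pixel covariance matrix."""
        vals = rng.normal(size=(60, 5, 5))
        field = _grid_field(vals)
        res = st.eof_decompose(field)
        x = vals.reshape(60, -1)
        x = x - x.mean(axis=0)
        eigvals = np.linalg.eigvalsh(x.T @ x)[::-1]
        frac = eigvals[:len(res.variance_fraction)] / eigvals.sum()
        np.testing.assert_allclose(res.variance_fraction, frac, atol=1e-10)


class TestPSD:
    def test_annual_peak(self):
        nt = int(20 * 365.25 / 8)
        t = np.arange(nt) * 8 / 365.25
        freq_domain = st.dominant_period_years(np.sin(2 * np.pi * t), 8 / 365.25)
        assert freq_domain == pytest.approx(1.0, rel=0.05)

    def test_semiannual_peak(self):
        nt = int(20 * 365.25 / 8)
        t = np.arange(nt) * 8 / 365.25
        period = st.dominant_period_years(np.sin(4 * np.pi * t), 8 / 365.25)
        assert period == pytest.approx(0.5, rel=0.05)

    def test_white_noise_has_no_dominant_peak(self):
        # periodogram ordinates of white noise are ~exponential, so the max of
        # ~250 ordinates sits near ln(250)/ln(2) ≈ 8× the median; a genuine
        # dominant line must stand far above that order-statistic level
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            x = np.random.default_rng(seed).normal(size=500)
            freq, power = st.psd_periodogram(x, 8 / 365.25)
            if power[freq > 0].max() > 20 * np.median(power[freq > 0]):
                hits += 1
        assert hits <= 0.05 * n_seeds + 1

    def test_interannual_mode_selection(self, rng):
        nt = int(12 * 365.25 / 8)  # 12 y puts the 4-y line on a frequency bin
        t = np.arange(nt) * 8 / 365.25
        ny, nx = 4, 5
        annual_pat = rng.normal(size=(ny, nx))
        slow_pat = rng.normal(size=(ny, nx))
        vals = (np.sin(2 * np.pi * t)[:, None, None] * annual_pat * 2.0
                + np.sin(2 * np.pi * t / 4.0)[:, None, None] * slow_pat)
        res = st.eof_decompose(_grid_field(vals), n_modes=4)
        modes = st.select_interannual_pcs(res)
        assert len(modes) >= 1
        pc = res.pcs.sel(mode=modes[0]).values
        assert st.dominant_period_years(pc, 8 / 365.25) == pytest.approx(4.0, rel=0.2)


class TestLowess:
    def test_line_in_line_out(self):
        y = 0.5 + 2.0 * np.arange(100.0)
        out = st.lowess_smooth(y, window=20)
        np.testing.assert_allclose(out, y, rtol=1e-8)

    def test_constant_preserved(self):
        out = st.lowess_smooth(np.full(50, 3.0), window=20)
        np.testing.assert_allclose(out, 3.0, rtol=1e-10)

    def test_step_becomes_monotone_transition(self):
        y = np.concatenate([np.zeros(40), np.ones(40)])
        out = st.lowess_smooth(y, window=20)
        assert np.all(np.diff(out) >= -1e-9)
        assert out[0] < 0.1 and out[-1] > 0.9

    def test_window_too_small(self):
        with pytest.raises(ValueError):
            st.lowess_smooth(np.arange(10.0), window=2)


class TestVariancePartition:
    @staticmethod
    def _balanced_design(month_share=0.6, n_years=4):
        months = np.arange(1, 13)
        alpha = 1.0
        # SS_month = n_years·Σa² = 24α², SS_year = 12·Σb²; Σb² = 5β², so
        # β² = 4α²/15 plants SS_year = 16α² and a 24/40 = 0.6 month share
        a = alpha * np.cos(2 * np.pi * months / 12)
        beta = alpha * np.sqrt(4.0 / 15.0)
        b = beta * (np.arange(n_years) - (n_years - 1) / 2)
        vals = (a[None, :] + b[:, None]).ravel()              # year-major
        times = pd.date_range("2000-01-01", periods=12 * n_years, freq="MS")
        return _grid_field(np.tile(vals[:, None, None], (1, 2, 2)),
                           start="2000-01-01", freq="MS"), times

    def test_planted_balanced_60_40_design_exact(self):
        """Noise-free orthogonal month/year design: fractions exactly 0.6/0.4."""
        field, _ = self._balanced_design()
        parts = st.variance_partition(field, monthly=True)
        np.testing.assert_allclose(parts["month_fraction"].values, 0.6, atol=1e-10)
        np.testing.assert_allclose(parts["year_fraction"].values, 0.4, atol=1e-10)
        np.testing.assert_allclose(parts["residual_fraction"].values, 0.0, atol=1e-10)

    def test_pure_seasonal_cycle(self):
        months = pd.date_range("2000-01-01", periods=36, freq="MS")
        vals = np.sin(2 * np.pi * months.month / 12.0)
        field = _grid_field(np.tile(vals.to_numpy()[:, None, None], (1, 2, 2)),
                            freq="MS")
        parts = st.variance_partition(field, monthly=True)
        np.testing.assert_allclose(parts["month_fraction"].values, 1.0, atol=1e-10)
        np.testing.assert_allclose(parts["year_fraction"].values, 0.0, atol=1e-10)

    def test_pure_year_blocks(self):
        years = np.repeat([1.0, 2.0, 4.0], 12)
        field = _grid_field(np.tile(years[:, None, None], (1, 2, 2)), freq="MS")
        parts = st.variance_partition(field, monthly=True)
        np.testing.assert_allclose(parts["year_fraction"].values, 1.0, atol=1e-10)
        np.testing.assert_allclose(parts["month_fraction"].values, 0.0, atol=1e-10)

    def test_fractions_bounded_and_subadditive(self, small_theta):
        parts = st.variance_partition(small_theta)
        for name in ("month_fraction", "year_fraction", "residual_fraction"):
            v = parts[name].values
            ok = np.isfinite(v)
            assert np.all((v[ok] >= 0) & (v[ok] <= 1))
        total = (parts["month_fraction"] + parts["year_fraction"]).values
        assert np.nanmax(total) <= 1.0 + 1e-8


class TestAnomalies:
    def test_monthly_anomaly_climatology_is_zero(self, small_theta):
        anom = st.anomaly(small_theta, mode="monthly")
        clim = anom.groupby("time.month").mean("time")
        assert float(np.nanmax(np.abs(clim.values))) < 1e-10

    def test_constant_field_zero_anomalies(self):
        field = _grid_field(np.full((48, 2, 2), 2.5), freq="MS")
        for mode in ("monthly", "annual"):
            anom = st.anomaly(field, mode=mode)
            np.testing.assert_allclose(anom.values, 0.0, atol=1e-12)

    def test_phase_composite_recovers_planted_pattern(self):
        nt = 12 * 6
        times = pd.date_range("2000-01-01", periods=nt, freq="MS")
        warm_years = [2001, 2003, 2005]
        pattern = np.array([[1.0, -1.0], [0.5, -0.5]])
        vals = np.zeros((nt, 2, 2))
        for i, ts in enumerate(times):
            if ts.year in warm_years:
                vals[i] = pattern
        field = _grid_field(vals, freq="MS")
        annual = st.anomaly(field, mode="annual")
        comp = st.phase_composite(annual, warm_years)
        np.testing.assert_allclose(comp.values, pattern / 2.0, atol=1e-10)


class TestClimateCorrelationAndRegions:
    def test_pc_equal_to_index(self):
        t = pd.date_range("2000-01-01", periods=100, freq="8D")
        ti = pd.date_range("1999-12-01", periods=40, freq="MS")
        idx = np.sin(np.arange(40) / 3.0)
        pc = np.interp(
            (t - t[0]).days / 365.25,
            (ti - t[0]).days / 365.25, idx)
        r, p = st.climate_index_correlation(t.values, pc, ti.values, idx)
        assert r == pytest.approx(1.0, abs=1e-10)
        r2, _ = st.climate_index_correlation(t.values, -pc, ti.values, idx)
        assert r2 == pytest.approx(-1.0, abs=1e-10)

    def test_independent_red_noise_low_correlation(self):
        rng = np.random.default_rng(1)
        t = pd.date_range("2000-01-01", periods=912, freq="8D")  # ~20 years
        pc = rng.normal(size=912)
        ti = pd.date_range("2000-01-01", periods=240, freq="MS")
        idx = rng.normal(size=240)
        r, _ = st.climate_index_correlation(t.values, pc, ti.values, idx)
        assert abs(r) < 0.15

    def test_region_labels_partition_ocean(self, small_scene):
        labels = st.region_labels(small_scene["z_no3"])
        vals = labels.values
        ocean = np.isfinite(small_scene["z_no3"].values)
        assert set(np.unique(vals[ocean])) <= {
            "N_highNut", "N_lowNut", "S_highNut", "S_lowNut"}
        assert np.all(vals[~ocean] == "")


class TestRegionalBootstrap:
    @staticmethod
    def _label_like(slopes):
        return xr.full_like(slopes, "", dtype=object).where(
            ~np.isfinite(slopes), "N_lowNut")

    def test_constant_region_zero_width_ci(self):
        slopes = xr.DataArray(np.full((4, 5), 0.01), dims=("lat", "lon"))
        labels = xr.DataArray(np.full((4, 5), "N_lowNut"), dims=("lat", "lon"))
        res = st.regional_trend_summary(slopes, labels, n_boot=200, seed=0)
        assert res["ci_lower"].iloc[0] == pytest.approx(0.01)
        assert res["ci_upper"].iloc[0] == pytest.approx(0.01)

    def test_ci_contains_sample_mean_and_scales(self, rng):
        slopes = xr.DataArray(rng.normal(0.002, 0.01, size=(8, 10)),
                              dims=("lat", "lon"))
        labels = xr.DataArray(np.where(np.arange(80).reshape(8, 10) < 40,
                                       "N_highNut", "S_lowNut"),
                              dims=("lat", "lon"))
        res = st.regional_trend_summary(slopes, labels, n_boot=2000, seed=1,
                                        display_scale=10.0)
        for _, row in res.iterrows():
            assert row["ci_lower"] <= row["mean"] <= row["ci_upper"]
        flat = slopes.values.ravel()
        assert res.set_index("region").loc["N_highNut", "mean"] == pytest.approx(
            10.0 * flat[:40].mean())
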