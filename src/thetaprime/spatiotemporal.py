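"""Geospatial statistics for gridded Θ′ (and SST) time series.

Per-pixel linear detrending and trends, EOF decomposition with PC power
spectra, lowess smoothing, month/year variance partitioning, monthly/annual
anomalies and phase composites, climate-index correlation, and bootstrapped
regional trend summaries.

All gridded inputs are :class:`xarray.DataArray` with dims ``(time, lat, lon)``
(missing cells NaN); time series are 1-D arrays or pandas Series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import signal, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "EOFResult",
    "TrendResult",
    "detrend_linear",
    "eof_decompose",
    "psd_periodogram",
    "dominant_period_years",
    "select_interannual_pcs",
    "lowess_smooth",
    "variance_partition",
    "anomaly",
    "phase_composite",
    "pixel_trend",
    "climate_index_correlation",
    "region_labels",
    "regional_trend_summary",
]


# --------------------------------------------------------------------------
# detrending and trends
# --------------------------------------------------------------------------

def _time_in_years(time_values: np.ndarray) -> np.ndarray:
    t = np.asarray(time_values)
    if np.issubdtype(t.dtype, np.datetime64):
        return ((t - t[0]) / np.timedelta64(1, "D")).astype(float) / 365.25
    return t.astype(float)


def _ols_slope_grid(y: np.ndarray, t: np.ndarray):
    """Per-column OLS of y (n_time × n_pix) on t; returns slope, intercept, stderr."""
    tc = t - t.mean()
    sxx = (tc ** 2).sum()
    valid = np.isfinite(y)
    # complete columns: vectorized
    slope = np.full(y.shape[1], np.nan)
    intercept = np.full(y.shape[1], np.nan)
    stderr = np.full(y.shape[1], np.nan)
    full = valid.all(axis=0)
    if full.any():
        yf = y[:, full]
        ym = yf.mean(axis=0)
        b = (tc @ (yf - ym)) / sxx
        a = ym - b * t.mean()
        resid = yf - (a + np.outer(t, b))
        dof = max(y.shape[0] - 2, 1)
        se = np.sqrt((resid ** 2).sum(axis=0) / dof / sxx)
        slope[full], intercept[full], stderr[full] = b, a, se
    # gappy columns: per-column fallback
    for j in np.nonzero(~full)[0]:
        m = valid[:, j]
        if m.sum() < 3:
            continue
        res = stats.linregress(t[m], y[m, j])
        slope[j], intercept[j], stderr[j] = res.slope, res.intercept, res.stderr
    return slope, intercept, stderr


def detrend_linear(field: xr.DataArray) -> tuple[xr.DataArray, xr.DataArray]:
    """Remove the per-pixel OLS linear trend; returns (detrended, slope).

    The fitted line (intercept included) is subtracted, so the detrended series
    also has zero mean per pixel.  Slopes are per year.  Pixels with < 3 valid
    time steps come back fully masked.
    """
    t = _time_in_years(field["time"].values)
    stacked = field.stack(space=("lat", "lon"))
    y = stacked.values
    slope, intercept, _ = _ols_slope_grid(y, t)
    fit = intercept[None, :] + np.outer(t, slope)
    det = stacked.copy(data=y - fit).unstack("space")
    slope_da = xr.DataArray(
        slope.reshape(field.sizes["lat"], field.sizes["lon"]),
        coords={"lat": field["lat"], "lon": field["lon"]},
        dims=("lat", "lon"), name="slope", attrs={"units": "per year"})
    return det.transpose(*field.dims), slope_da


@dataclass
class TrendResult:
    """Per-pixel OLS trends with domain summaries."""

    slope: xr.DataArray        # units: field units per year
    intercept: xr.DataArray
    stderr: xr.DataArray
    median_slope: float
    positive_area_fraction: float


def pixel_trend(field: xr.DataArray) -> TrendResult:
    """Per-pixel OLS slope over the record, domain median and warming-area fraction."""
    t = _time_in_years(field["time"].values)
    stacked = field.stack(space=("lat", "lon"))
    slope, intercept, stderr = _ols_slope_grid(stacked.values, t)
    shape = (field.sizes["lat"], field.sizes["lon"])
    coords = {"lat": field["lat"], "lon": field["lon"]}
    mk = lambda v, n: xr.DataArray(v.reshape(shape), coords=coords,
                                   dims=("lat", "lon"), name=n)
    finite = np.isfinite(slope)
    return TrendResult(
        slope=mk(slope, "slope"),
        intercept=mk(intercept, "intercept"),
        stderr=mk(stderr, "stderr"),
        median_slope=float(np.median(slope[finite])) if finite.any() else np.nan,
        positive_area_fraction=float((slope[finite] > 0).mean()) if finite.any() else np.nan,
    )


# --------------------------------------------------------------------------
# EOF decomposition
# --------------------------------------------------------------------------

@dataclass
class EOFResult:
    """EOF modes of a detrended field.

    ``modes``: (mode, lat, lon) spatial loadings (unit vectors over retained
    pixels, NaN where excluded); ``pcs``: (mode, time) principal components in
    field units; ``variance_fraction``: per-mode share of total variance.
    Reconstruction of the input (over retained pixels) is
    ``sum_k modes_k * pcs_k``.
    """

    modes: xr.DataArray
    pcs: xr.DataArray
    variance_fraction: np.ndarray
    singular_values: np.ndarray

    def reconstruct(self, n_modes: int | None = None) -> xr.DataArray:
        k = n_modes or self.modes.sizes["mode"]
        return (self.modes.isel(mode=slice(0, k)) *
                self.pcs.isel(mode=slice(0, k))).sum("mode", skipna=False)


def eof_decompose(field: xr.DataArray, n_modes: int | None = None,
                  max_missing_fraction: float = 0.2,
                  demean: bool = True) -> EOFResult:
    """EOF (SVD) decomposition of a (time, lat, lon) field.

    Pixels with more than ``max_missing_fraction`` missing time steps are
    excluded listwise (any remaining gap also excludes the pixel).  Each mode's
    sign is fixed so its spatial loading of maximum absolute value is positive.
    Zero-variance modes are dropped.
    """
    if field.sizes["time"] < 2:
        raise ValueError("EOF needs at least 2 time steps")
    stacked = field.stack(space=("lat", "lon"))
    y = stacked.values  # time × space
    missing = ~np.isfinite(y)
    keep = missing.mean(axis=0) <= max_missing_fraction
    keep &= ~missing.any(axis=0)
    if keep.sum() < 2:
        raise ValueError("EOF needs at least 2 fully observed pixels")
    x = y[:, keep]
    if demean:
        x = x - x.mean(axis=0, keepdims=True)
    # x = U S Vt with U (time) and Vt (space); spatial modes are rows of Vt
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    nonzero = s > s[0] * 1e-12 if s.size and s[0] > 0 else s > 0
    u, s, vt = u[:, nonzero], s[nonzero], vt[nonzero]
    total_var = (s ** 2).sum()
    var_frac = s ** 2 / total_var if total_var > 0 else s * 0.0
    k = min(n_modes or s.size, s.size)
    u, s, vt, var_frac = u[:, :k], s[:k], vt[:k], var_frac[:k]

    # sign convention: dominant spatial loading positive
    flip = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    pcs = (u * s) * flip[None, :]   # time × mode, field units

    modes_full = np.full((k, y.shape[1]), np.nan)
    modes_full[:, keep] = vt
    modes = xr.DataArray(
        modes_full, dims=("mode", "space"),
        coords={"mode": np.arange(1, k + 1), "space": stacked["space"]},
    ).unstack("space")
    pcs_da = xr.DataArray(pcs.T, dims=("mode", "time"),
                          coords={"mode": np.arange(1, k + 1),
                                  "time": field["time"]})
    return EOFResult(modes=modes, pcs=pcs_da, variance_fraction=var_frac,
                     singular_values=s)


def psd_periodogram(pc, sample_spacing_years: float) -> tuple[np.ndarray, np.ndarray]:
    """Periodogram PSD of a PC; frequencies in cycles per year."""
    x = np.asarray(pc, dtype=float)
    freq, power = signal.periodogram(x, fs=1.0 / sample_spacing_years)
    return freq, power


def dominant_period_years(pc, sample_spacing_years: float) -> float:
    """Period (years) of the periodogram peak, ignoring the zero frequency."""
    freq, power = psd_periodogram(pc, sample_spacing_years)
    pos = freq > 0
    f = freq[pos][np.argmax(power[pos])]
    return 1.0 / f


def select_interannual_pcs(result: EOFResult,
                           period_threshold_years: float = 1.5) -> list[int]:
    """Mode numbers whose PC has a dominant period longer than the threshold.

    PC numbering of interannual modes is dataset-dependent (e.g. modes 5 and 6
    in the satellite record), so modes are selected by their spectral content,
    not by a fixed index.  Returned in descending variance order.
    """
    t = result.pcs["time"].values
    dt = float(np.median(np.diff(_time_in_years(t))))
    out = []
    for m in result.pcs["mode"].values:
        pc = result.pcs.sel(mode=m).values
        if dominant_period_years(pc, dt) > period_threshold_years:
            out.append(int(m))
    return out


# --------------------------------------------------------------------------
# smoothing, variance partition, anomalies
# --------------------------------------------------------------------------

def lowess_smooth(series, window: int = 20):
    """Lowess smoother: local weighted linear (first-degree) fit, tricube weights.

    ``window`` is the moving-window size in points (default 20), converted to
    the equivalent local-regression bandwidth fraction.
    """
    y = np.asarray(series, dtype=float)
    if window < 3:
        raise ValueError("window must be >= 3")
    n = y.size
    frac = min(1.0, window / n)
    x = np.arange(n, dtype=float)
    out = _sm_lowess(y, x, frac=frac, it=0, return_sorted=False)
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index)
    return out


def _monthly_bin(field: xr.DataArray) -> xr.DataArray:
    """Calendar-month means of composite midpoints."""
    return field.resample(time="MS").mean()


def variance_partition(field: xr.DataArray, monthly: bool | None = None
                       ) -> xr.Dataset:
    """Per-pixel month/year variance decomposition.

    8-day composites are first binned to calendar months; each pixel's monthly
    series is decomposed with a two-factor fixed-effects model (month-of-year,
    n = 12 levels; year, one level per calendar year).  Fractions are the
    factor sum of squares over the total sum of squares — type-II sums of
    squares for unbalanced (gappy) pixels, which reduce to the textbook
    orthogonal decomposition when the design is balanced.

    Returns a Dataset with ``month_fraction`` (seasonal), ``year_fraction``
    (interannual) and ``residual_fraction``.
    """
    needs_binning = monthly is None or not monthly
    data = _monthly_bin(field) if needs_binning else field
    t = pd.DatetimeIndex(data["time"].values)
    months = t.month.to_numpy()
    years = t.year.to_numpy()
    uyears = np.unique(years)
    if uyears.size < 2:
        raise ValueError("variance partition needs >= 2 years of data")

    # dummy design matrices (full-rank, intercept + effects coding)
    n = len(t)
    xm = np.zeros((n, 11))
    for k, m in enumerate(range(2, 13)):
        xm[months == m, k] = 1.0
        xm[months == 1, k] = -1.0
    xy = np.zeros((n, uyears.size - 1))
    for k, yv in enumerate(uyears[1:]):
        xy[years == yv, k] = 1.0
        xy[years == uyears[0], k] = -1.0
    one = np.ones((n, 1))
    x_month = np.hstack([one, xm])
    x_year = np.hstack([one, xy])
    x_both = np.hstack([one, xm, xy])

    stacked = data.stack(space=("lat", "lon"))
    y = stacked.values
    npix = y.shape[1]
    month_frac = np.full(npix, np.nan)
    year_frac = np.full(npix, np.nan)
    resid_frac = np.full(npix, np.nan)

    def rss(x, yy):
        beta, res, rank, _ = np.linalg.lstsq(x, yy, rcond=None)
        r = yy - x @ beta
        return (r ** 2).sum(axis=0)

    valid = np.isfinite(y)
    full = valid.all(axis=0)
    groups = [(full, np.ones(n, dtype=bool))]
    # gappy pixels grouped by identical missingness pattern for vectorization
    gap_idx = np.nonzero(~full & (valid.sum(axis=0) >= x_both.shape[1] + 2))[0]
    patterns: dict[bytes, list[int]] = {}
    for j in gap_idx:
        patterns.setdefault(valid[:, j].tobytes(), []).append(j)
    for key, js in patterns.items():
        groups.append((np.isin(np.arange(npix), js), valid[:, js[0]]))

    for colmask, rowmask in groups:
        if not colmask.any():
            continue
        yy = y[np.ix_(rowmask, colmask)]
        xb, xmn, xyr = x_both[rowmask], x_month[rowmask], x_year[rowmask]
        tss = ((yy - yy.mean(axis=0)) ** 2).sum(axis=0)
        rss_both = rss(xb, yy)
        ss_month = rss(xyr, yy) - rss_both   # month | year  (type II)
        ss_year = rss(xmn, yy) - rss_both    # year  | month (type II)
        with np.errstate(invalid="ignore", divide="ignore"):
            month_frac[colmask] = np.clip(ss_month / tss, 0.0, 1.0)
            year_frac[colmask] = np.clip(ss_year / tss, 0.0, 1.0)
            resid_frac[colmask] = np.clip(rss_both / tss, 0.0, 1.0)

    shape = (data.sizes["lat"], data.sizes["lon"])
    coords = {"lat": data["lat"], "lon": data["lon"]}
    return xr.Dataset(
        {
            "month_fraction": (("lat", "lon"), month_frac.reshape(shape)),
            "year_fraction": (("lat", "lon"), year_frac.reshape(shape)),
            "residual_fraction": (("lat", "lon"), resid_frac.reshape(shape)),
        },
        coords=coords,
    )


def anomaly(field: xr.DataArray, mode: str = "monthly") -> xr.DataArray:
    """Anomaly fields.

    ``monthly``: subtract each pixel's month-of-year climatology (input kept at
    its native time resolution).  ``annual``: calendar-year means minus the
    record mean per pixel.
    """
    if mode == "monthly":
        clim = field.groupby("time.month").mean("time")
        return (field.groupby("time.month") - clim).drop_vars("month")
    if mode == "annual":
        yearly = field.groupby("time.year").mean("time")
        return yearly - field.mean("time")
    raise ValueError(f"unknown anomaly mode {mode!r}")


def phase_composite(annual_anomalies: xr.DataArray, years) -> xr.DataArray:
    """Mean annual anomaly over a listed set of years (e.g. a PDO phase)."""
    return annual_anomalies.sel(year=list(years)).mean("year")


# --------------------------------------------------------------------------
# climate indices and regional summaries
# --------------------------------------------------------------------------

def climate_index_correlation(pc_times, pc, index_times, index
                              ) -> tuple[float, float]:
    """Pearson correlation between a PC and a climate index.

    The (typically monthly) index is linearly interpolated onto the PC time
    stamps; returns (r, two-sided p).
    """
    tp = _time_in_years(np.asarray(pc_times))
    ti = np.asarray(index_times)
    if np.issubdtype(ti.dtype, np.datetime64):
        ti = ((ti - np.asarray(pc_times)[0]) / np.timedelta64(1, "D")).astype(float) / 365.25
    else:
        ti = ti.astype(float)
    interp = np.interp(tp, ti, np.asarray(index, dtype=float))
    inside = (tp >= ti.min()) & (tp <= ti.max())
    r, p = stats.pearsonr(np.asarray(pc, dtype=float)[inside], interp[inside])
    return float(r), float(p)


def region_labels(z_no3: xr.DataArray, split_depth_m: float = 50.0) -> xr.DataArray:
    """Hemisphere × nutrient-class labels from the nutricline-depth map.

    ``highNut``: nutricline shallower than the split depth (50 m); ``lowNut``:
    deeper.  Labels are 'N_highNut', 'N_lowNut', 'S_highNut', 'S_lowNut'; land
    pixels get ''.
    """
    hemi = xr.where(z_no3["lat"] >= 0, "N_", "S_")
    nut = xr.where(z_no3 <= split_depth_m, "highNut", "lowNut")
    labels = (hemi + nut).where(np.isfinite(z_no3), "")
    labels.name = "region"
    return labels


def regional_trend_summary(slopes: xr.DataArray, labels: xr.DataArray,
                           n_boot: int = 10_000, seed: int = 0,
                           display_scale: float = 1.0) -> pd.DataFrame:
    """Mean trend per region with 95% percentile-bootstrap CIs.

    Bootstraps pixels independently within each region (``n_boot`` resamples).
    ``display_scale`` multiplies the reported numbers (Θ′ trends are shown ×10
    to sit on the same axis as SST trends).
    """
    rng = np.random.default_rng(seed)
    rows = []
    flat_s = slopes.values.ravel()
    flat_l = np.asarray(labels.values).ravel()
    for region in sorted(set(flat_l) - {""}):
        vals = flat_s[(flat_l == region) & np.isfinite(flat_s)]
        if vals.size == 0:
            continue
        boot_means = np.empty(n_boot)
        done = 0
        while done < n_boot:  # chunked to bound the resample matrix size
            k = min(2000, n_boot - done)
            idx = rng.integers(0, vals.size, size=(k, vals.size))
            boot_means[done:done + k] = vals[idx].mean(axis=1)
            done += k
        lo, hi = np.percentile(boot_means, [2.5, 97.5])
        rows.append({
            "region": region,
            "n_pixels": int(vals.size),
            "mean": vals.mean() * display_scale,
            "ci_lower": lo * display_scale,
            "ci_upper": hi * display_scale,
        })
    return pd.DataFrame(rows)
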