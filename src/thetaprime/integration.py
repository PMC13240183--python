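"""Satellite–in-situ integration: matchups, timescale scan, variance attribution.

Matches point biomarker samples to the gridded Θ′ field over spatiotemporal
windows, scans window sizes for the characteristic timescale of the
physiology–genomics correspondence, quantifies the Θ′ variance explained by
nutricline depth vs genomic biomarkers with random-forest models, and computes
SCCG-normalized gene-trait correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .synthetic import GeneAbundanceTable

__all__ = [
    "MatchupWindow",
    "SPATIAL_WINDOW_MENU",
    "TEMPORAL_HALF_WIDTHS_DAYS",
    "VarianceAttribution",
    "colocate",
    "timescale_scan",
    "variance_attribution",
    "normalize_gene_abundance",
    "trait_correlation",
]

#: Spatial averaging windows of the matchup menu: pixel boxes and degree boxes.
SPATIAL_WINDOW_MENU = ("1x1", "3x3", "5x5", "1deg", "2deg", "5deg")

#: Temporal half-widths of the matchup menu, days (±2 to ±30 in 2-day steps).
TEMPORAL_HALF_WIDTHS_DAYS = tuple(range(2, 31, 2))


@dataclass(frozen=True)
class MatchupWindow:
    """A spatiotemporal averaging window centered on a sample.

    ``spatial`` is one of the menu entries (``'3x3'`` pixels, ``'2deg'`` = a
    2°×2° box) and ``temporal_half_width_days`` the ± half-width in days (the
    characteristic 40-day window is ±20 d).  Degree windows are centered on the
    sample's coordinates, not snapped to pixel boundaries.
    """

    spatial: str = "2deg"
    temporal_half_width_days: float = 20.0

    def __post_init__(self):
        if self.temporal_half_width_days < 0:
            raise ValueError("temporal half-width must be >= 0")
        s = self.spatial
        if not (s in SPATIAL_WINDOW_MENU or s.endswith("deg") or "x" in s):
            raise ValueError(f"unknown spatial window {s!r}")


def _spatial_masks(window: MatchupWindow, lat: np.ndarray, lon: np.ndarray,
                   sample_lat: float, sample_lon: float):
    """Index ranges (pixel windows) or boolean masks (degree windows)."""
    s = window.spatial
    if s.endswith("deg"):
        half = float(s[:-3]) / 2.0
        lat_ok = np.abs(lat - sample_lat) <= half
        dlon = np.abs((lon - sample_lon + 180.0) % 360.0 - 180.0)
        lon_ok = dlon <= half
        return lat_ok, lon_ok
    k = int(s.split("x")[0])
    if k % 2 != 1:
        raise ValueError("pixel windows must have odd size")
    ic = int(np.argmin(np.abs(lat - sample_lat)))
    jc = int(np.argmin(np.abs(np.abs((lon - sample_lon + 180.0) % 360.0 - 180.0))))
    h = k // 2
    lat_ok = np.zeros(lat.size, dtype=bool)
    lat_ok[max(0, ic - h):ic + h + 1] = True
    lon_ok = np.zeros(lon.size, dtype=bool)
    for j in range(jc - h, jc + h + 1):
        lon_ok[j % lon.size] = True
    return lat_ok, lon_ok


def colocate(theta_prime: xr.DataArray, samples: pd.DataFrame,
             window: MatchupWindow) -> pd.DataFrame:
    """Matched Θ′ per sample: unweighted mean over the spatiotemporal window.

    Returns the input frame plus ``theta_prime`` (NaN where the window is fully
    masked) and ``n_cells`` (count of contributing unmasked cells).
    """
    lat = theta_prime["lat"].values
    lon = theta_prime["lon"].values
    tdays = (theta_prime["time"].values - theta_prime["time"].values[0]) \
        / np.timedelta64(1, "D")
    if window.spatial.endswith("deg"):
        width = float(window.spatial[:-3])
        if width > (lat.max() - lat.min()) + (lat[1] - lat[0]):
            raise ValueError("spatial window larger than the grid")
    vals = theta_prime.transpose("time", "lat", "lon").values

    out_theta = np.empty(len(samples))
    out_n = np.empty(len(samples), dtype=int)
    sample_days = (pd.DatetimeIndex(samples["date"]).values
                   - theta_prime["time"].values[0]) / np.timedelta64(1, "D")
    for i, (slat, slon, sday) in enumerate(zip(samples["lat"].to_numpy(),
                                               samples["lon"].to_numpy(),
                                               sample_days)):
        tmask = np.abs(tdays - sday) <= window.temporal_half_width_days
        lat_ok, lon_ok = _spatial_masks(window, lat, lon, slat, slon)
        box = vals[np.ix_(tmask, lat_ok, lon_ok)]
        finite = np.isfinite(box)
        out_n[i] = int(finite.sum())
        out_theta[i] = box[finite].mean() if finite.any() else np.nan
    result = samples.copy()
    result["theta_prime"] = out_theta
    result["n_cells"] = out_n
    return result


@dataclass
class VarianceAttribution:
    """Out-of-bag variance explained by nested random-forest predictor sets."""

    r2_nutricline_only: float
    r2_full: float
    r2_nutricline_only_inbag: float
    r2_full_inbag: float
    n_samples: int
    n_trees: int
    seed: int


def _fit_rf(x: np.ndarray, y: np.ndarray, n_trees: int, seed: int
            ) -> tuple[float, float]:
    """Random forest fit; returns (out-of-bag R², in-bag R²)."""
    rf = RandomForestRegressor(n_estimators=n_trees, oob_score=True,
                               bootstrap=True, random_state=seed, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # few-tree fits may miss OOB coverage
        rf.fit(x, y)
    return float(rf.oob_score_), float(rf.score(x, y))


def variance_attribution(matched: pd.DataFrame,
                         nutricline_col: str = "z_no3",
                         omega_cols: tuple = ("omega_nh", "omega_nm", "omega_ph",
                                              "omega_feh", "omega_fem"),
                         target_col: str = "theta_prime",
                         n_trees: int = 500, seed: int = 0,
                         min_samples: int = 30) -> VarianceAttribution:
    """Θ′ variance explained by nutricline depth alone vs nutricline + biomarkers.

    Two random forests (``n_trees`` each, package-default split parameters) are
    fit on complete cases; variance explained is out-of-bag R² (in-bag R² is
    reported alongside for transparency).
    """
    cols = [nutricline_col, *omega_cols, target_col]
    df = matched[cols].replace([np.inf, -np.inf], np.nan).dropna()
    if len(df) < min_samples:
        raise ValueError(f"need >= {min_samples} complete cases, got {len(df)}")
    y = df[target_col].to_numpy()
    r2_nut, r2_nut_in = _fit_rf(df[[nutricline_col]].to_numpy(), y, n_trees, seed)
    r2_full, r2_full_in = _fit_rf(df[[nutricline_col, *omega_cols]].to_numpy(),
                                  y, n_trees, seed)
    return VarianceAttribution(
        r2_nutricline_only=r2_nut, r2_full=r2_full,
        r2_nutricline_only_inbag=r2_nut_in, r2_full_inbag=r2_full_in,
        n_samples=len(df), n_trees=n_trees, seed=seed)


def timescale_scan(theta_prime: xr.DataArray, samples: pd.DataFrame,
                   spatial_windows: tuple = ("3x3",),
                   temporal_half_widths: tuple = TEMPORAL_HALF_WIDTHS_DAYS,
                   predictor_cols: tuple = ("omega_nh", "omega_nm", "omega_ph",
                                            "omega_feh", "omega_fem", "z_no3"),
                   n_trees: int = 500, seed: int = 0) -> pd.DataFrame:
    """Scan matchup windows for the characteristic correspondence timescale.

    For each (spatial, temporal) window the samples are colocated with Θ′ and a
    random forest predicts matched Θ′ from the biomarkers + nutricline; the
    out-of-bag variance explained is recorded.  The window maximizing it is the
    characteristic matchup scale (≈ ±20 d / 2°×2° in the satellite record).

    Returns a tidy frame (spatial, temporal_half_width_days, r2_oob, n) with
    attrs ``best_spatial`` and ``best_temporal_half_width_days``.
    """
    if len(predictor_cols) < 2:
        raise ValueError("need at least 2 predictors")
    if len(samples) < 30:
        raise ValueError("need at least 30 samples")
    rows = []
    for s in spatial_windows:
        for th in temporal_half_widths:
            w = MatchupWindow(spatial=s, temporal_half_width_days=th)
            matched = colocate(theta_prime, samples, w)
            df = matched[[*predictor_cols, "theta_prime"]].replace(
                [np.inf, -np.inf], np.nan).dropna()
            if len(df) < 30:
                rows.append({"spatial": s, "temporal_half_width_days": th,
                             "r2_oob": np.nan, "n": len(df)})
                continue
            r2, _ = _fit_rf(df[list(predictor_cols)].to_numpy(),
                            df["theta_prime"].to_numpy(), n_trees, seed)
            rows.append({"spatial": s, "temporal_half_width_days": th,
                         "r2_oob": r2, "n": len(df)})
    out = pd.DataFrame(rows)
    best = out.loc[out["r2_oob"].idxmax()]
    out.attrs["best_spatial"] = best["spatial"]
    out.attrs["best_temporal_half_width_days"] = float(
        best["temporal_half_width_days"])
    return out


def normalize_gene_abundance(table: GeneAbundanceTable
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SCCG normalization: copies per genome and per-gene z-scores.

    Each gene's read coverage is divided by the sample's mean single-copy
    core-gene coverage, giving copies per genome (invariant to per-sample
    sequencing depth); z-scores standardize each gene across samples (mean 0,
    sd 1).  Samples with non-positive SCCG coverage are dropped with a warning.
    """
    ok = table.sccg_mean > 0
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} sample(s) with zero SCCG coverage")
    cov = table.coverage.loc[ok]
    copies = cov.div(table.sccg_mean[ok], axis=0)
    sd = copies.std(axis=0, ddof=1)
    z = (copies - copies.mean(axis=0)) / sd.replace(0.0, np.nan)
    return copies, z


def trait_correlation(z_scores: pd.DataFrame, theta_prime: pd.Series,
                      min_pairs: int = 3) -> pd.DataFrame:
    """Per-gene Pearson correlation between normalized abundance and matched Θ′.

    Genes are ranked by r (most negative first — the severe-stress traits).
    Constant or too-sparse genes report NaN.
    """
    theta = theta_prime.reindex(z_scores.index)
    rows = []
    for gene in z_scores.columns:
        zi = z_scores[gene]
        pair = pd.concat([zi, theta], axis=1).dropna()
        if len(pair) < min_pairs or pair.iloc[:, 0].nunique() < 2 \
                or pair.iloc[:, 1].nunique() < 2:
            rows.append({"gene": gene, "r": np.nan, "p": np.nan, "n": len(pair)})
            continue
        r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
        rows.append({"gene": gene, "r": float(r), "p": float(p), "n": len(pair)})
    return pd.DataFrame(rows).sort_values("r").reset_index(drop=True)


def partial_dependence_theta(matched: pd.DataFrame, feature: str,
                             predictor_cols: tuple,
                             target_col: str = "theta_prime",
                             grid_resolution: int = 20,
                             n_trees: int = 500, seed: int = 0) -> pd.DataFrame:
    """Generic partial dependence of Θ′ on one predictor from the full RF."""
    from sklearn.inspection import partial_dependence as _pd

    df = matched[[*predictor_cols, target_col]].replace(
        [np.inf, -np.inf], np.nan).dropna()
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(df[list(predictor_cols)].to_numpy(), df[target_col].to_numpy())
    res = _pd(rf, df[list(predictor_cols)].to_numpy(),
              [list(predictor_cols).index(feature)],
              grid_resolution=grid_resolution)
    return pd.DataFrame({feature: res["grid_values"][0],
                         "theta_prime": res["average"][0]})
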