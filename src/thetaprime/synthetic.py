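"""Synthetic-ocean generator: gridded scenes, biomarker samples, gene tables.

Emulates the statistical structure the Θ′ analysis assumes — a latent nutrient
stress field driven by nutricline depth, modulated by seasonal cycles, one
interannual climate mode, a long-term trend, fast stress fluctuations and
multiplicative observation noise — so every downstream stage (index
computation, matchups, EOF/variance decomposition, trend and bootstrap
statistics) can be exercised at desk scale with known ground truth.

The latent stress field is

    S(x, t) = g(Z(x)) · seasonal(x, t) · mode(x, t) · (1 + ρ(x)·t) · fast(x, t)

with g a monotone decreasing map from nutricline depth Z to mean Θ′ (deep
nutricline → low Θ′, i.e. strong stress), and the scene's observable fields are
built so that recomputing Θ′ = Θ_photo/Θ_obs returns S times the observation
noise exactly (and S itself when ``noise_cv = 0``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr

from . import index as _index

__all__ = [
    "SceneSpec",
    "OmegaRule",
    "DEFAULT_OMEGA_RULES",
    "GeneAbundanceTable",
    "generate_scene",
    "sample_biomarkers",
    "generate_gene_table",
    "generate_climate_index",
    "planted_variance_shares",
]


@dataclass
class SceneSpec:
    """Parameters of a synthetic scene.

    Spatial/temporal layout defaults follow the satellite analysis domain:
    40°S–40°N at 1°, 8-day composites over 20 years.  Stress-map parameters are
    set so mean Θ′ spans ≈ 0.5 (nutricline deeper than 150 m) to ≈ 3.5 (shallow
    or absent nutricline).
    """

    lat_min: float = -40.0
    lat_max: float = 40.0
    lat_step: float = 1.0
    lon_min: float = 0.0
    lon_max: float = 360.0
    lon_step: float = 1.0
    n_years: float = 20.0
    time_step_days: float = 8.0
    start: str = "2002-07-04"

    # nutricline-depth map (m): deep in gyre centers, shallow at the equatorial
    # upwelling band and poleward edges
    z_deep: float = 175.0
    z_shallow: float = 30.0

    # monotone stress map g(Z) = stress_min + stress_range / (1 + e^{(Z-z_mid)/z_scale})
    stress_min: float = 0.5
    stress_range: float = 3.0
    z_mid: float = 80.0
    z_scale: float = 25.0

    # temporal structure
    seasonal_amp: float = 0.35          # annual cycle amplitude (hemisphere-phased)
    semiannual_amp: float = 0.25        # tropical semiannual amplitude
    mode_amp: float = 0.15              # interannual climate-mode amplitude
    mode_periods_years: tuple = (3.4, 5.3)
    trend_rel_mean: float = -0.001      # mean relative Θ′ trend, year⁻¹
    trend_rel_amp: float = 0.003        # spatial spread of the relative trend
    stress_cv: float = 0.15             # fast (per-composite) latent stress fluctuation
    noise_cv: float = 0.05              # multiplicative observation noise on Θ_obs

    # SST trend (°C year⁻¹): mean + spatial spread (some regions cool)
    sst_trend_mean: float = 0.023
    sst_trend_amp: float = 0.03

    # rectangular "continents" (lat0, lat1, lon0, lon1); empty tuple = no land
    land_boxes: tuple = ((-40.0, 12.0, 288.0, 312.0),)

    seed: int = 0


@dataclass
class OmegaRule:
    """Logistic response of one genomic stress marker to latent stress.

    ``omega = offset + sign / (1 + exp((x - center)/width)) + noise`` where x is
    the windowed latent stress S̄ (``on='stress'``) or nutricline depth
    (``on='z_no3'``).  ``sign=0`` plants a stress-independent marker.
    """

    sign: float = 1.0
    center: float = 1.5
    width: float = 0.5
    noise_sd: float = 0.05
    on: str = "stress"


# High N stress and high/medium Fe stress markers are elevated where latent
# stress is strong (low Θ′ / shallow nutricline); P-stress markers are elevated
# in low-stress (deep-nutricline, high Θ′) waters — mirroring the observed
# biogeography of elemental stress types.
DEFAULT_OMEGA_RULES: dict[str, OmegaRule] = {
    "omega_nh": OmegaRule(sign=+1.0, center=1.5, width=0.5, on="stress"),
    "omega_nm": OmegaRule(sign=+1.0, center=2.5, width=0.7, on="stress"),
    "omega_ph": OmegaRule(sign=-1.0, center=1.8, width=0.6, on="stress"),
    "omega_feh": OmegaRule(sign=-1.0, center=60.0, width=20.0, on="z_no3"),
    "omega_fem": OmegaRule(sign=-1.0, center=100.0, width=30.0, on="z_no3"),
}


@dataclass
class GeneAbundanceTable:
    """Per-sample flexible-gene coverages with the SCCG normalizer.

    ``coverage``: samples × genes read-coverage frame; ``sccg_mean``: mean
    single-copy core-gene coverage per sample; ``planted_effects``: per-gene
    stress coefficient used to plant the trait–Θ′ association (ground truth).
    """

    coverage: pd.DataFrame
    sccg_mean: pd.Series
    planted_effects: pd.Series


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(0.0, sigma, size=size) - sigma ** 2 / 2.0)


def _fractional_year(times: np.ndarray) -> np.ndarray:
    t = pd.DatetimeIndex(times)
    year_start = pd.to_datetime(t.year.astype(str) + "-01-01")
    year_len = np.where(t.is_leap_year, 366.0, 365.0)
    frac = ((t - year_start).days + (t - year_start).seconds / 86400.0) / year_len
    return np.asarray(frac, dtype=float)


def _mode_index(times: np.ndarray, spec: SceneSpec,
                rng: np.random.Generator) -> np.ndarray:
    """Planted interannual climate-mode series (zero mean, unit sd)."""
    ty = (times - times[0]) / np.timedelta64(1, "D") / 365.25
    p1, p2 = spec.mode_periods_years
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    idx = np.sin(2 * np.pi * ty / p1 + ph1) + 0.6 * np.sin(2 * np.pi * ty / p2 + ph2)
    idx = idx - idx.mean()
    sd = idx.std()
    return idx / sd if sd > 0 else idx


def _nutricline_map(lat: np.ndarray, lon: np.ndarray, spec: SceneSpec) -> np.ndarray:
    """Smooth nutricline-depth field: deep subtropical gyres, shallow equator/edges."""
    la, lo = np.meshgrid(lat, lon, indexing="ij")
    gyre = np.exp(-((np.abs(la) - 22.0) / 12.0) ** 2)
    zonal = 0.75 + 0.25 * np.cos(np.deg2rad(2.0 * lo))
    return spec.z_shallow + (spec.z_deep - spec.z_shallow) * gyre * zonal


def stress_from_nutricline(z_no3, spec: SceneSpec | None = None):
    """Monotone decreasing map g(Z) from nutricline depth to mean Θ′."""
    spec = spec or SceneSpec()
    z = np.where(np.isinf(z_no3), 0.0, z_no3)  # absent nutricline == shallowest
    return spec.stress_min + spec.stress_range / (1.0 + np.exp((z - spec.z_mid) / spec.z_scale))


def generate_scene(spec: SceneSpec | None = None) -> xr.Dataset:
    """Generate a gridded scene with a planted latent stress field.

    Returns an :class:`xarray.Dataset` with observable variables ``chl``,
    ``c_phyto``, ``par``, ``kpar``, ``mld``, ``sst`` and ground-truth variables
    ``stress_true`` (latent S including fast fluctuations, excluding observation
    noise), ``z_no3``, ``trend_true`` (planted absolute Θ′ slope, year⁻¹),
    ``sst_trend_true``, ``mode_pattern`` and ``climate_index``.  Recomputing
    Θ′ = Θ_photo/Θ_obs from the observables returns ``stress_true`` times
    mean-one lognormal observation noise (bit-exact equality at ``noise_cv=0``).
    """
    spec = spec or SceneSpec()
    rng = np.random.default_rng(spec.seed)

    lat = np.arange(spec.lat_min + spec.lat_step / 2, spec.lat_max, spec.lat_step)
    lon = np.arange(spec.lon_min + spec.lon_step / 2, spec.lon_max, spec.lon_step)
    n_times = int(round(spec.n_years * 365.25 / spec.time_step_days))
    times = (np.datetime64(spec.start) +
             (np.arange(n_times) * spec.time_step_days * 24 * 3600).astype("timedelta64[s]"))
    if lat.size < 2 or lon.size < 2 or n_times < 2:
        warnings.warn("degenerate scene (single pixel or time step)")

    fy = _fractional_year(times)
    ty = (times - times[0]) / np.timedelta64(1, "D") / 365.25

    la3 = lat[None, :, None]
    lo3 = lon[None, None, :]
    fy3 = fy[:, None, None]
    ty3 = ty[:, None, None]

    # --- latent stress -----------------------------------------------------
    z_no3 = _nutricline_map(lat, lon, spec)
    base = stress_from_nutricline(z_no3, spec)[None, :, :]

    tropical = np.exp(-(la3 / 12.0) ** 2)
    annual = spec.seasonal_amp * (la3 / spec.lat_max) * np.cos(2 * np.pi * (fy3 - 0.47))
    semi = spec.semiannual_amp * tropical * np.cos(4 * np.pi * (fy3 - 0.2))
    seasonal = 1.0 + annual + semi

    mode_pattern = (np.sin(np.deg2rad(lo3 - 200.0)) *
                    np.exp(-(la3 / 25.0) ** 2))            # zonal tropical dipole
    climate_index = _mode_index(times, spec, rng)
    mode = 1.0 + spec.mode_amp * mode_pattern * climate_index[:, None, None]

    trend_rel = (spec.trend_rel_mean +
                 spec.trend_rel_amp * np.sin(np.deg2rad(4.0 * lat))[:, None] *
                 np.cos(np.deg2rad(1.5 * lon))[None, :])
    trend = 1.0 + trend_rel[None, :, :] * ty3

    shape = (n_times, lat.size, lon.size)
    fast = _lognormal_factor(rng, spec.stress_cv, shape)
    stress_true = base * seasonal * mode * trend * fast

    # --- observable physics fields ----------------------------------------
    par = ((52.0 - 0.4 * np.abs(la3)) *
           (1.0 + 0.25 * (la3 / spec.lat_max) * np.cos(2 * np.pi * (fy3 - 0.47))))
    mld = ((25.0 + 0.9 * np.abs(la3)) *
           (1.0 - 0.6 * (la3 / spec.lat_max) * np.cos(2 * np.pi * (fy3 - 0.47))))
    kpar = (0.045 + 0.015 * np.exp(-z_no3 / 60.0))[None, :, :] * np.ones(shape)
    par = par * np.ones(shape)
    mld = mld * np.ones(shape)

    th_photo = _index.theta_photo(par, kpar, mld)
    obs_noise = _lognormal_factor(rng, spec.noise_cv, shape)
    th_obs = th_photo / (stress_true * obs_noise)

    chl = (0.07 + 0.25 * np.exp(-z_no3 / 40.0))[None, :, :] * np.ones(shape)
    c_phyto = th_obs * chl

    sst_trend = (spec.sst_trend_mean +
                 spec.sst_trend_amp * np.sin(np.deg2rad(3.0 * lat + 30.0))[:, None] *
                 np.cos(np.deg2rad(2.0 * lon))[None, :])
    sst = (29.0 - 0.011 * la3 ** 2 +
           1.5 * (la3 / spec.lat_max) * np.cos(2 * np.pi * (fy3 - 0.6)) +
           sst_trend[None, :, :] * ty3 +
           rng.normal(0.0, 0.3, size=shape))

    ds = xr.Dataset(
        {
            "chl": (("time", "lat", "lon"), chl, {"units": "mg m-3"}),
            "c_phyto": (("time", "lat", "lon"), c_phyto, {"units": "mg m-3"}),
            "par": (("time", "lat", "lon"), par, {"units": "mol quanta m-2 day-1"}),
            "kpar": (("time", "lat", "lon"), kpar, {"units": "m-1"}),
            "mld": (("time", "lat", "lon"), mld, {"units": "m"}),
            "sst": (("time", "lat", "lon"), sst, {"units": "degC"}),
            "stress_true": (("time", "lat", "lon"), stress_true,
                            {"long_name": "planted latent stress S (ground truth)"}),
            "z_no3": (("lat", "lon"), z_no3, {"units": "m"}),
            "trend_true": (("lat", "lon"), base[0] * trend_rel,
                           {"units": "year-1",
                            "long_name": "planted absolute theta-prime slope"}),
            "sst_trend_true": (("lat", "lon"), sst_trend, {"units": "degC year-1"}),
            "mode_pattern": (("lat", "lon"), mode_pattern[0]),
            "climate_index": (("time",), climate_index),
        },
        coords={"time": times, "lat": lat, "lon": lon},
        attrs={
            "seed": spec.seed,
            "time_step_days": spec.time_step_days,
            "scene_spec": json.dumps(asdict(spec)),
        },
    )

    for la0, la1, lo0, lo1 in spec.land_boxes:
        land = ((ds.lat >= la0) & (ds.lat <= la1) &
                (ds.lon >= lo0) & (ds.lon <= lo1))
        for name, var in ds.data_vars.items():
            if set(("lat", "lon")) <= set(var.dims):
                ds[name] = var.where(~land)
    return ds


def recompute_theta_prime(scene: xr.Dataset, **kwargs) -> xr.DataArray:
    """Run the Θ′ computation on a scene's observable fields."""
    tp = _index.theta_photo(scene["par"], scene["kpar"], scene["mld"], **kwargs)
    to = _index.theta_obs(scene["c_phyto"], scene["chl"])
    out = _index.stress_index(tp, to)
    out.name = "theta_prime"
    return out


def _windowed_stress(scene: xr.Dataset, it: int, ila: int, ilo: int,
                     half_days: float) -> float:
    """Mean latent stress at a pixel over ± half_days around time index it."""
    t = scene.time.values
    sel = np.abs((t - t[it]) / np.timedelta64(1, "D")) <= half_days
    return float(scene["stress_true"].values[sel, ila, ilo].mean())


def sample_biomarkers(scene: xr.Dataset, n: int,
                      rule: dict[str, OmegaRule] | None = None,
                      mode: str = "cruise",
                      response_window_days: float = 40.0,
                      seed: int | None = None) -> pd.DataFrame:
    """Draw georeferenced biomarker samples co-varying with the latent stress.

    Ω values are logistic functions of the latent stress averaged over the
    planted characteristic response window (default 40 days full width) or of
    nutricline depth, plus Gaussian noise, per :class:`OmegaRule`.  ``mode``
    selects cruise-track-like contiguous sampling (the field-campaign geometry)
    or uniform random sampling (for unit tests).

    Returns a DataFrame with lat, lon, date, the five Ω columns, z_no3 and the
    ground-truth windowed stress (``stress_true``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rule = rule if rule is not None else DEFAULT_OMEGA_RULES
    rng = np.random.default_rng(scene.attrs.get("seed", 0) + 1 if seed is None else seed)

    ocean = np.isfinite(scene["z_no3"].values)
    iy_ocean, ix_ocean = np.nonzero(ocean)
    n_times = scene.sizes["time"]
    if iy_ocean.size == 0:
        raise ValueError("scene has no ocean pixels")
    if n > iy_ocean.size * n_times:
        raise ValueError("n exceeds the scene's ocean-cell capacity")

    nlat, nlon = scene.sizes["lat"], scene.sizes["lon"]
    positions: list[tuple[int, int, int]] = []
    if mode == "uniform":
        picks = rng.integers(0, iy_ocean.size, size=n)
        its = rng.integers(0, n_times, size=n)
        positions = [(int(t), int(iy_ocean[p]), int(ix_ocean[p]))
                     for t, p in zip(its, picks)]
    elif mode == "cruise":
        while len(positions) < n:
            p = rng.integers(0, iy_ocean.size)
            ila, ilo = int(iy_ocean[p]), int(ix_ocean[p])
            it = int(rng.integers(0, n_times))
            heading = rng.uniform(0, 2 * np.pi)
            for _ in range(min(40, n - len(positions))):
                if ocean[ila, ilo]:
                    positions.append((it, ila, ilo))
                heading += rng.normal(0, 0.3)
                ila = int(np.clip(ila + round(np.sin(heading)), 0, nlat - 1))
                ilo = int((ilo + round(np.cos(heading))) % nlon)
                it = min(it + 1, n_times - 1)
        positions = positions[:n]
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")

    half = response_window_days / 2.0
    rows = []
    for it, ila, ilo in positions:
        s_bar = _windowed_stress(scene, it, ila, ilo, half)
        z = float(scene["z_no3"].values[ila, ilo])
        row = {
            "lat": float(scene.lat.values[ila]),
            "lon": float(scene.lon.values[ilo]),
            "date": pd.Timestamp(scene.time.values[it]),
            "z_no3": z,
            "stress_true": s_bar,
        }
        for name, r in rule.items():
            x = s_bar if r.on == "stress" else z
            logistic = 1.0 / (1.0 + np.exp((x - r.center) / r.width))
            row[name] = r.sign * logistic + rng.normal(0.0, r.noise_sd)
        rows.append(row)
    return pd.DataFrame(rows)


def generate_gene_table(samples: pd.DataFrame, n_genes: int = 60,
                        planted_effects: np.ndarray | None = None,
                        coverage_cv: float = 0.2,
                        seed: int = 0) -> GeneAbundanceTable:
    """Build a flexible-gene coverage table with planted trait–stress effects.

    Per-gene copies-per-genome respond log-linearly to the standardized latent
    stress of each sample with coefficient β (positive, negative or zero —
    the three trait classes); read coverage is copies × the sample's mean
    single-copy core-gene (SCCG) coverage × lognormal noise, so SCCG
    normalization must recover the planted copies up to noise.
    """
    rng = np.random.default_rng(seed)
    if planted_effects is None:
        planted_effects = np.resize([0.6, -0.6, 0.0], n_genes)
    planted_effects = np.asarray(planted_effects, dtype=float)
    if planted_effects.size != n_genes:
        raise ValueError("planted_effects length must equal n_genes")

    s = samples["stress_true"].to_numpy()
    s_z = (s - s.mean()) / s.std() if s.std() > 0 else np.zeros_like(s)
    sccg = pd.Series(
        20.0 * _lognormal_factor(rng, 0.3, len(samples)), index=samples.index,
        name="sccg_mean")
    copies = np.exp(np.outer(s_z, planted_effects))          # samples × genes
    noise = _lognormal_factor(rng, coverage_cv, copies.shape)
    genes = [f"gene_{i:04d}" for i in range(n_genes)]
    coverage = pd.DataFrame(copies * noise * sccg.to_numpy()[:, None],
                            index=samples.index, columns=genes)
    return GeneAbundanceTable(coverage=coverage, sccg_mean=sccg,
                              planted_effects=pd.Series(planted_effects, index=genes))


def generate_climate_index(scene: xr.Dataset, n_distractors: int = 2,
                           seed: int | None = None) -> pd.DataFrame:
    """Monthly climate-index series for the scene's planted interannual mode.

    Returns the planted mode index resampled to calendar-month means (column
    ``mode``) plus optional AR(1) red-noise distractor indices uncorrelated
    with it by construction.
    """
    rng = np.random.default_rng(scene.attrs.get("seed", 0) + 2 if seed is None else seed)
    s = pd.Series(scene["climate_index"].values,
                  index=pd.DatetimeIndex(scene.time.values))
    monthly = s.resample("MS").mean().dropna()
    out = pd.DataFrame({"mode": monthly})
    # moderate memory keeps spurious correlation with the quasi-periodic mode
    # small over a ~240-month record
    phi = 0.5
    for k in range(n_distractors):
        x = np.empty(len(monthly))
        x[0] = rng.normal()
        for i in range(1, len(x)):
            x[i] = phi * x[i - 1] + rng.normal(0, np.sqrt(1 - phi ** 2))
        out[f"distractor_{k}"] = x
    return out


def planted_variance_shares(scene: xr.Dataset) -> dict[str, float]:
    """Analytic seasonal/interannual variance shares of the planted stress.

    Runs the month/year variance partition on the noise-free latent stress and
    aggregates over ocean pixels, for comparison with the shares recovered from
    recomputed (noisy) Θ′.
    """
    from . import spatiotemporal as _st
    parts = _st.variance_partition(scene["stress_true"])
    return {
        "seasonal": float(parts["month_fraction"].mean().values),
        "interannual": float(parts["year_fraction"].mean().values),
        "residual": float(parts["residual_fraction"].mean().values),
    }
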