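"""NetCDF scene I/O, regridding and cross-sensor bias harmonization.

One CF-style NetCDF schema is shared by the synthetic generator and any
"real" data source, so the pipeline is data-source-agnostic: variables
``chl``, ``c_phyto`` (or ``bbp_443``), ``par``, ``kpar``, ``mld``, ``sst``
on (time, lat, lon), with units attributes and NaN for missing cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import xarray as xr

__all__ = [
    "REQUIRED_VARS",
    "SensorBias",
    "read_scene",
    "write_scene",
    "regrid_downscale",
    "apply_sensor_bias",
]

REQUIRED_VARS = ("chl", "c_phyto", "par", "kpar", "mld")

EXPECTED_UNITS = {
    "chl": "mg m-3",
    "c_phyto": "mg m-3",
    "par": "mol quanta m-2 day-1",
    "kpar": "m-1",
    "mld": "m",
    "sst": "degC",
}


@dataclass
class SensorBias:
    """Cross-mission offsets added to SeaWiFS products to match MODIS-Aqua.

    Defaults are the overlap-period (2003–2007) mean differences: Chl offset
    −0.012 mg m⁻³ (i.e. SeaWiFS Chl minus 0.012) and b_bp443 offset
    +1.71 × 10⁻⁵ m⁻¹.
    """

    chl_offset: float = -0.012
    bbp_offset: float = 1.71e-5


def write_scene(scene: xr.Dataset, path) -> None:
    """Write a scene to NetCDF (values, masks, coordinates, attributes)."""
    scene.to_netcdf(path)


def read_scene(path, check_schema: bool = True) -> xr.Dataset:
    """Read a scene, validating the variable schema and units attributes.

    A missing required variable raises a ``ValueError`` naming it; a units
    attribute differing from the schema's convention warns but does not fail.
    """
    ds = xr.open_dataset(path).load()
    if check_schema:
        missing = [v for v in REQUIRED_VARS if v not in ds.data_vars]
        if missing:
            raise ValueError(f"scene file {path} lacks required variable(s): "
                             f"{', '.join(missing)}")
        for name, units in EXPECTED_UNITS.items():
            if name in ds and ds[name].attrs.get("units", units) != units:
                warnings.warn(f"variable {name!r} has units "
                              f"{ds[name].attrs['units']!r}, expected {units!r}")
    return ds


def _coarsen_factors(da: xr.DataArray, target_deg: float) -> tuple[int, int]:
    lat_res = float(abs(da["lat"].values[1] - da["lat"].values[0]))
    lon_res = float(abs(da["lon"].values[1] - da["lon"].values[0]))
    fy = max(1, int(round(target_deg / lat_res)))
    fx = max(1, int(round(target_deg / lon_res)))
    return fy, fx


def regrid_downscale(scene: xr.Dataset, target_deg: float = 1.0,
                     period_days: float | None = 8.0) -> xr.Dataset:
    """Down-scale to a coarser regular grid (and optionally coarser composites).

    Each coarse cell is the unweighted mean of its contributing finer cells
    (and composites within each period); cells with no valid contributors stay
    masked.  Applying the same target twice is the identity.
    """
    fy, fx = _coarsen_factors(next(iter(scene.data_vars.values())), target_deg)
    out = scene
    if fy > 1 or fx > 1:
        out = out.coarsen(lat=fy, lon=fx, boundary="trim").mean()
    if period_days is not None and "time" in out.dims and out.sizes["time"] > 1:
        dt = float((out["time"].values[1] - out["time"].values[0])
                   / np.timedelta64(1, "D"))
        ft = max(1, int(round(period_days / dt)))
        if ft > 1:
            out = out.coarsen(time=ft, boundary="trim").mean()
    out.attrs.update(scene.attrs)
    return out


def apply_sensor_bias(scene: xr.Dataset, bias: SensorBias | None = None
                      ) -> xr.Dataset:
    """Apply cross-mission bias offsets to Chl (and b_bp443 when present).

    Sets a provenance flag; a second application raises rather than silently
    double-correcting.
    """
    bias = bias or SensorBias()
    if scene.attrs.get("sensor_bias_applied"):
        raise ValueError("sensor bias already applied to this scene")
    out = scene.copy()
    out["chl"] = scene["chl"] + bias.chl_offset
    if "bbp_443" in scene:
        out["bbp_443"] = scene["bbp_443"] + bias.bbp_offset
    out.attrs["sensor_bias_applied"] = 1
    out.attrs["sensor_bias_chl_offset"] = bias.chl_offset
    out.attrs["sensor_bias_bbp_offset"] = bias.bbp_offset
    return out
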