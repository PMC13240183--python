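"""Photoacclimation model and the satellite nutrient-stress index Θ′.

The carbon-to-chlorophyll ratio Θ = C:Chl of a phytoplankton community reflects
both photoacclimation to the mixed-layer light environment and the down-regulation
of cellular chlorophyll under nutrient stress.  The index separates the two:

* ``theta_obs``   — Θ_obs, the observed C:Chl from satellite retrievals of
  phytoplankton carbon and chlorophyll-a.
* ``theta_photo`` — Θ_photo, the C:Chl expected from photoacclimation alone,
  computed mechanistically from PAR, K_PAR and mixed-layer depth as a deep-mixing
  baseline Θ_DM times a shallow-mixing correction ΔΘ_SM.
* ``stress_index`` — Θ′ = Θ_photo / Θ_obs (lower Θ′ = stronger nutrient stress),
  plus the two rejected formulations (inverse and normalized difference).

All functions vectorize over numpy arrays and xarray objects; missing cells
(NaN) propagate through arithmetic untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal
import warnings

import numpy as np

__all__ = [
    "THETA_DM_DEFAULT",
    "NUTRICLINE_ABSENT",
    "DEEP_MIXING_OPTICAL_DEPTH",
    "ThetaTriple",
    "MldResult",
    "median_mixed_layer_irradiance",
    "shallow_mixing_correction",
    "theta_photo",
    "theta_obs",
    "stress_index",
    "nutricline_depth",
    "mld_from_density_profile",
    "kpar_from_k490",
]

#: Deep-mixing baseline C:Chl, mgC mgChl⁻¹.
THETA_DM_DEFAULT = 150.0

#: Sentinel for a nutricline that never reaches the threshold anywhere in the
#: profile ("absent" nutricline).  Deliberately distinct from NaN (missing data):
#: an absent nutricline is an observation, not a gap.
NUTRICLINE_ABSENT = np.inf

#: Dimensionless optical depth K_PAR·MLD at which the shallow-mixing correction
#: equals 1 exactly: 2·ln(20) ≈ 5.99, i.e. ≈ 6 optical depths.
DEEP_MIXING_OPTICAL_DEPTH = 2.0 * np.log(20.0)

IndexVariant = Literal["ratio", "inverse", "normdiff"]


@dataclass
class ThetaTriple:
    """Per-cell Θ_obs, Θ_photo and Θ′ with the model constants that produced them."""

    theta_obs: np.ndarray
    theta_photo: np.ndarray
    theta_prime: np.ndarray
    theta_dm: float = THETA_DM_DEFAULT
    delta_sm: np.ndarray | None = None


@dataclass
class MldResult:
    """Mixed-layer depth from a density profile, with a bottom-limited flag."""

    depth: float
    bottom_limited: bool


def _check_nonnegative(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError(f"{name} must be non-negative")


def median_mixed_layer_irradiance(par, kpar, mld):
    """Median irradiance within the mixed layer, I_ML = PAR·e^(−K_PAR·MLD/2).

    Parameters
    ----------
    par : array_like
        Daily integrated PAR, mol quanta m⁻² day⁻¹ (≥ 0).
    kpar : array_like
        Diffuse attenuation coefficient for PAR, m⁻¹ (> 0).
    mld : array_like
        Mixed-layer depth, m (≥ 0).
    """
    _check_nonnegative("par", par)
    _check_nonnegative("mld", mld)
    karr = np.asarray(kpar, dtype=float)
    if np.any(karr[np.isfinite(karr)] <= 0):
        raise ValueError("kpar must be strictly positive")
    return par * np.exp(-kpar * mld / 2.0)


def shallow_mixing_correction(par, iml):
    """Shallow-mixing correction ΔΘ_SM = (1 + e^(−0.15·PAR)) / (1 + e^(−3·I_ML)).

    Bounded in (0, 2]; equals 1 when the exponents agree (0.15·PAR = 3·I_ML),
    which happens at PAR = 0 and, for any PAR, at K_PAR·MLD = 2·ln(20).
    """
    _check_nonnegative("par", par)
    _check_nonnegative("iml", iml)
    p = np.asarray(par, dtype=float)
    i = np.asarray(iml, dtype=float)
    both = np.isfinite(p) & np.isfinite(i)
    if np.any(i[both] > p[both] * (1 + 1e-12) + 1e-12):
        raise ValueError("iml cannot exceed par (light cannot amplify with depth)")
    return (1.0 + np.exp(-0.15 * par)) / (1.0 + np.exp(-3.0 * iml))


def theta_photo(par, kpar, mld, theta_dm: float = THETA_DM_DEFAULT,
                clamp_deep_mixing: bool = False):
    """Photoacclimation C:Chl, Θ_photo = Θ_DM × ΔΘ_SM.

    Θ_DM is the deep-mixing baseline (default 150 mgC mgChl⁻¹); ΔΘ_SM corrects
    for shallower mixing via the median mixed-layer irradiance.  By default the
    correction is applied at all mixed-layer depths exactly as the closed-form
    expression reads; ``clamp_deep_mixing=True`` instead pins ΔΘ_SM = 1 wherever
    K_PAR·MLD exceeds ≈ 6 optical depths (the deep-mixing criterion), the
    alternative reading of the deep-mixing baseline.
    """
    if theta_dm <= 0:
        raise ValueError("theta_dm must be positive")
    iml = median_mixed_layer_irradiance(par, kpar, mld)
    delta = shallow_mixing_correction(par, iml)
    if clamp_deep_mixing:
        deep = np.asarray(kpar, dtype=float) * np.asarray(mld, dtype=float) \
            >= DEEP_MIXING_OPTICAL_DEPTH
        delta = np.where(deep, 1.0, delta)
    return theta_dm * delta


def theta_obs(c_phyto, chl):
    """Observed C:Chl, Θ_obs = C_phyto / Chl (mgC mgChl⁻¹).

    Cells where either retrieval is non-positive are masked (NaN) rather than
    propagated as nonsense ratios.  An all-masked result warns but does not fail.
    """
    c = np.asarray(c_phyto, dtype=float)
    ch = np.asarray(chl, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((c > 0) & (ch > 0), c / ch, np.nan)
    if out.size and not np.any(np.isfinite(out)):
        warnings.warn("theta_obs: all cells masked (no positive C_phyto/Chl pairs)")
    # hand back an xarray object when one came in
    if hasattr(c_phyto, "dims"):
        return c_phyto.copy(data=out)
    return out


def stress_index(theta_photo, theta_obs, variant: IndexVariant = "ratio"):
    """Nutrient-stress index from Θ_photo and Θ_obs.

    ``ratio`` (the index used throughout): Θ′ = Θ_photo/Θ_obs — linear in the
    nutrient-regulated division rate.  ``inverse`` (Θ_obs/Θ_photo) and
    ``normdiff`` ((Θ_obs−Θ_photo)/Θ_photo) are the rejected curvilinear variants,
    kept for comparison.
    """
    if variant == "ratio":
        return theta_photo / theta_obs
    if variant == "inverse":
        return theta_obs / theta_photo
    if variant == "normdiff":
        return (theta_obs - theta_photo) / theta_photo
    raise ValueError(f"unknown stress-index variant {variant!r}; "
                     "expected 'ratio', 'inverse' or 'normdiff'")


def _check_profile(depth: np.ndarray, value: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    depth = np.asarray(depth, dtype=float)
    value = np.asarray(value, dtype=float)
    if depth.ndim != 1 or depth.size < 2 or depth.shape != value.shape:
        raise ValueError("profile needs ≥ 2 matching (depth, value) levels")
    if np.any(depth < 0):
        raise ValueError("profile depths must be non-negative")
    if np.any(np.diff(depth) <= 0):
        raise ValueError("profile depths must be strictly increasing")
    return depth, value


def nutricline_depth(depth, nitrate, threshold: float = 3.0) -> float:
    """Nutricline depth Z_NO3: shallowest depth where nitrate reaches *threshold* μM.

    Linear interpolation between the bracketing profile levels.  A surface value
    already at/above the threshold returns 0; a profile that never reaches it
    returns :data:`NUTRICLINE_ABSENT` (the "shallow (or absent) nutricline" case,
    encoded distinctly from missing data).
    """
    depth, no3 = _check_profile(depth, nitrate)
    if no3[0] >= threshold:
        return 0.0
    above = np.nonzero(no3 >= threshold)[0]
    if above.size == 0:
        return NUTRICLINE_ABSENT
    j = above[0]
    d0, d1 = depth[j - 1], depth[j]
    v0, v1 = no3[j - 1], no3[j]
    return float(d0 + (threshold - v0) / (v1 - v0) * (d1 - d0))


def mld_from_density_profile(depth, density, delta: float = 0.03,
                             ref_depth: float = 10.0) -> MldResult:
    """Mixed-layer depth by the density-threshold criterion.

    Shallowest depth (below the reference depth) where potential density exceeds
    the density at *ref_depth* by *delta* kg m⁻³, located by linear interpolation.
    If the threshold is never exceeded the deepest level is returned with
    ``bottom_limited=True``.
    """
    depth, rho = _check_profile(depth, density)
    if not (depth[0] <= ref_depth <= depth[-1]):
        raise ValueError(f"profile must span the reference depth {ref_depth} m")
    rho_ref = float(np.interp(ref_depth, depth, rho))
    target = rho_ref + delta
    below = depth >= ref_depth
    d, r = depth[below], rho[below]
    if ref_depth not in d:
        d = np.insert(d, 0, ref_depth)
        r = np.insert(r, 0, rho_ref)
    above = np.nonzero(r >= target)[0]
    if above.size == 0:
        return MldResult(depth=float(depth[-1]), bottom_limited=True)
    j = above[0]
    if j == 0 or r[j] == target:
        return MldResult(depth=float(d[j]), bottom_limited=False)
    d0, d1, v0, v1 = d[j - 1], d[j], r[j - 1], r[j]
    return MldResult(depth=float(d0 + (target - v0) / (v1 - v0) * (d1 - d0)),
                     bottom_limited=False)


def kpar_from_k490(k490, passthrough: bool = False):
    """Diffuse attenuation for PAR from K_490.

    Uses the Morel-style polynomial K_PAR = 0.0864 + 0.884·K490 − 0.00137/K490
    (monotone increasing for K490 > 0).  ``passthrough=True`` returns the input
    unchanged, for datasets that already carry K_PAR.
    """
    k = np.asarray(k490, dtype=float)
    if np.any(k[np.isfinite(k)] <= 0):
        raise ValueError("k490 must be strictly positive")
    if passthrough:
        return k490
    return 0.0864 + 0.884 * k490 - 0.00137 / k490


def theta_fields(par, kpar, mld, c_phyto, chl,
                 theta_dm: float = THETA_DM_DEFAULT,
                 clamp_deep_mixing: bool = False,
                 variant: IndexVariant = "ratio") -> ThetaTriple:
    """Convenience wrapper: compute Θ_obs, Θ_photo and Θ′ in one call."""
    tp = theta_photo(par, kpar, mld, theta_dm=theta_dm,
                     clamp_deep_mixing=clamp_deep_mixing)
    to = theta_obs(c_phyto, chl)
    return ThetaTriple(theta_obs=to, theta_photo=tp,
                       theta_prime=stress_index(tp, to, variant=variant),
                       theta_dm=theta_dm, delta_sm=tp / theta_dm)
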