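"""Chemostat-style photoacclimation simulation comparing stress-index formulations.

Cellular Chl:C is set jointly by growth irradiance (photoacclimation: more
pigment at low light) and by the nutrient-regulated division rate (cells shed
chlorophyll in proportion to a nutrient-imposed growth penalty).  The model here
is a two-endmember mixture:

    Chl:C(I, f) = chlc_dark · e^(−I/b)  +  f · chlc_sat · (1 − e^(−I/b))

so that every nutrient condition converges on the single dark value
``chlc_dark`` as irradiance → 0 (division is entirely light-limited there, hence
independent of nutrients), while at saturating irradiance Chl:C scales in direct
proportion to the relative nutrient-regulated division rate ``f`` (f = 1 is the
nutrient-limited baseline; f > 1 more nutrients, f < 1 fewer).

From these curves the three candidate stress indices are formed with
Θ_obs = 1/Chl:C(I, f) and Θ_photo = 1/Chl:C(I, 1):

* ratio      Θ_photo/Θ_obs            — exactly linear in f (≈ f at saturating I),
* inverse    Θ_obs/Θ_photo            — convex, curvilinear in f,
* normdiff  (Θ_obs−Θ_photo)/Θ_photo   — inverse − 1, same curvature.

The linearity of the ratio variant is the reason it is the index adopted for the
satellite analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AcclimationModel", "chlc_curve", "division_rate", "index_response"]


@dataclass
class AcclimationModel:
    """Parametric light/nutrient Chl:C model.

    Parameters
    ----------
    chlc_dark : float
        Chl:C to which all nutrient conditions converge as irradiance → 0,
        mgChl mgC⁻¹.
    chlc_sat : float
        Baseline (f = 1) Chl:C at saturating irradiance, mgChl mgC⁻¹.
    i_decay : float
        e-folding irradiance of the photoacclimation transition,
        μmol photon m⁻² s⁻¹.
    mu_sat : float
        Light-saturated, nutrient-limited division rate of the baseline, day⁻¹.
    i_sat : float
        Irradiance below which division becomes light-limited,
        μmol photon m⁻² s⁻¹.
    """

    chlc_dark: float = 0.05
    chlc_sat: float = 0.01
    i_decay: float = 75.0
    mu_sat: float = 0.75
    i_sat: float = 200.0

    def __post_init__(self) -> None:
        if self.chlc_dark <= 0 or self.chlc_sat <= 0:
            raise ValueError("Chl:C endmembers must be positive")
        if self.mu_sat <= 0 or self.i_sat <= 0 or self.i_decay <= 0:
            raise ValueError("mu_sat, i_sat and i_decay must be positive")

    def chlc_base(self, irradiance):
        """Baseline (f = 1) Chl:C vs growth irradiance, monotone decreasing."""
        return chlc_curve(self, irradiance, 1.0)


def chlc_curve(model: AcclimationModel, irradiance, f: float):
    """Chl:C at growth irradiance(s) for nutrient multiplier ``f``.

    Curves for all f > 0 converge on ``model.chlc_dark`` at zero irradiance and
    approach ``f · model.chlc_sat`` at saturating irradiance.
    """
    if f <= 0:
        raise ValueError("nutrient multiplier f must be positive")
    i = np.asarray(irradiance, dtype=float)
    if np.any(i < 0):
        raise ValueError("irradiance must be non-negative")
    w = np.exp(-i / model.i_decay)
    return model.chlc_dark * w + f * model.chlc_sat * (1.0 - w)


def division_rate(model: AcclimationModel, irradiance, f: float):
    """Division rate μ (day⁻¹): μ = f · μ_sat · min(1, ramp(I/i_sat)).

    The light-limitation ramp is a saturating exponential normalized to reach
    1 exactly at ``i_sat``, so division is light-saturated above ``i_sat`` and
    zero in the dark; nondecreasing in both I and f.
    """
    if f <= 0:
        raise ValueError("nutrient multiplier f must be positive")
    i = np.asarray(irradiance, dtype=float)
    if np.any(i < 0):
        raise ValueError("irradiance must be non-negative")
    alpha = 3.0  # shape of the sub-saturation ramp
    ramp = (1.0 - np.exp(-alpha * i / model.i_sat)) / (1.0 - np.exp(-alpha))
    return f * model.mu_sat * np.minimum(1.0, ramp)


def index_response(model: AcclimationModel, f_grid, irradiance: float = 2000.0
                   ) -> pd.DataFrame:
    """Evaluate the three stress-index formulations across nutrient multipliers.

    For each f, Θ_obs = 1/Chl:C(I, f) and Θ_photo = 1/Chl:C(I, 1); the returned
    frame has columns ``f``, ``ratio``, ``inverse``, ``normdiff`` plus the
    division rate ``mu``.
    """
    f_grid = np.asarray(f_grid, dtype=float)
    if np.any(f_grid <= 0):
        raise ValueError("all f values must be positive")
    chlc_photo = float(chlc_curve(model, irradiance, 1.0))
    rows = []
    for f in f_grid:
        chlc_obs = float(chlc_curve(model, irradiance, f))
        theta_obs = 1.0 / chlc_obs
        theta_photo = 1.0 / chlc_photo
        ratio = theta_photo / theta_obs
        rows.append({
            "f": f,
            "ratio": ratio,
            "inverse": 1.0 / ratio,
            "normdiff": 1.0 / ratio - 1.0,
            "mu": float(division_rate(model, irradiance, f)),
        })
    return pd.DataFrame(rows)
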