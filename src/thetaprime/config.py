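"""Run configuration: every numeric constant of the analysis in one place.

Defaults are the values used throughout the satellite analysis (deep-mixing
baseline 150 mgC mgChl⁻¹, 3 μM nutricline threshold, 0.03 kg m⁻³ MLD density
criterion, the SeaWiFS−MODIS bias offsets, 500-tree forests, the 2°×2°/±20-day
characteristic matchup window, the 50 m highNut/lowNut split and 10⁴
bootstraps).  A YAML file overrides any subset of keys.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, fields

import yaml

__all__ = ["Config", "load_config"]


@dataclass
class Config:
    theta_dm: float = 150.0                   # mgC mgChl⁻¹
    clamp_deep_mixing: bool = False
    nutricline_threshold_uM: float = 3.0
    mld_delta_kgm3: float = 0.03
    mld_ref_depth_m: float = 10.0
    seawifs_chl_offset: float = -0.012        # mg m⁻³, added to SeaWiFS Chl
    seawifs_bbp_offset: float = 1.71e-5       # m⁻¹, added to SeaWiFS b_bp443
    n_trees: int = 500
    matchup_spatial: str = "2deg"
    matchup_half_width_days: float = 20.0     # the 40-day characteristic window
    region_split_depth_m: float = 50.0
    n_boot: int = 10_000
    eof_max_missing_fraction: float = 0.2
    lowess_window: int = 20

    def hash(self) -> str:
        """Short stable digest of the configuration, for run logs."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | None = None) -> Config:
    """Load a Config, overriding defaults with keys from a YAML file."""
    cfg = Config()
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(Config)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for k, v in data.items():
        setattr(cfg, k, v)
    return cfg
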