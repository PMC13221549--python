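"""Calibration, timing and tolerance configuration objects.

These hold the scanner- and protocol-level constants of a single-time-point
SPECT/CT dosimetry workflow: the cps→MBq cross-calibration factor, the CT
number→mass-density conversion table, the imaging time post administration,
per-organ effective half-lives, and the contour-agreement tolerances.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class DensityTable:
    """Ordered (HU, g/cm3) pairs for piecewise-linear density conversion.

    HU must be strictly increasing, densities non-negative, and the table
    must anchor water: HU 0 maps to 1.0 g/cm3.
    """

    hu: tuple[float, ...]
    density: tuple[float, ...]

    def __post_init__(self):
        self.hu = tuple(float(x) for x in self.hu)
        self.density = tuple(float(x) for x in self.density)
        if len(self.hu) != len(self.density):
            raise ValueError("hu and density must have equal length")
        if len(self.hu) < 2:
            raise ValueError("density table needs at least 2 points")
        if any(b <= a for a, b in zip(self.hu, self.hu[1:])):
            raise ValueError("HU values must be strictly increasing")
        if any(d < 0 for d in self.density):
            raise ValueError("densities must be non-negative")
        interp_at_0 = float(np.interp(0.0, self.hu, self.density))
        if abs(interp_at_0 - 1.0) > 1e-9:
            raise ValueError(
                f"table must map HU 0 to 1.0 g/cm3 (water), got {interp_at_0}"
            )


#: Gammex-like tissue characterization curve (lung → soft tissue → bone).
DEFAULT_DENSITY_TABLE = DensityTable(
    hu=(-1000.0, -800.0, -500.0, -100.0, 0.0, 55.0, 300.0, 1000.0, 3000.0),
    density=(0.001, 0.20, 0.50, 0.93, 1.0, 1.06, 1.16, 1.61, 2.60),
)


@dataclass
class CalibrationConfig:
    """Scanner calibration for count-rate quantification.

    ccf : cross-calibration factor in cps/MBq (measured on a cylindrical
        phantom of known activity; 9.64 for a Symbia T6, 9.92 for a T16).
    density_table : HU → g/cm3 conversion pairs.
    psf_fwhm_mm : effective isotropic system blur used by the simulator.
    """

    ccf: float = 9.64
    density_table: DensityTable = field(default_factory=lambda: DEFAULT_DENSITY_TABLE)
    psf_fwhm_mm: float = 15.0

    def __post_init__(self):
        if self.ccf <= 0:
            raise ValueError(f"ccf must be positive, got {self.ccf}")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")


#: Per-organ effective half-lives (h) of the single-time-point method.
DEFAULT_T_EFF_HOURS = {
    "kidney_right": 51.0,
    "kidney_left": 51.0,
    "spleen": 68.0,
    "liver": 67.0,
}


@dataclass
class TimingParams:
    """Imaging time and effective half-life for one organ.

    t_hours : imaging time post administration (h).
    t_eff_hours : organ effective half-life (h); only the bias ratio needs
        it — the single-time-point dose integral itself does not.
    """

    t_hours: float = 24.49
    t_eff_hours: float = 51.0

    def __post_init__(self):
        if self.t_hours <= 0:
            raise ValueError("t_hours must be > 0")
        if self.t_eff_hours <= 0:
            raise ValueError("t_eff_hours must be > 0")

    @property
    def lambda_eff(self) -> float:
        """Effective decay constant ln2 / t_eff, in 1/h."""
        return math.log(2.0) / self.t_eff_hours


@dataclass
class ToleranceCriteria:
    """Contour-agreement acceptance thresholds: DSC >= 0.800, HD and MDA <= 3.0 mm."""

    dsc_min: float = 0.800
    hd_max_mm: float = 3.0
    mda_max_mm: float = 3.0

    def __post_init__(self):
        if not (0 < self.dsc_min <= 1):
            raise ValueError("dsc_min must lie in (0, 1]")
        if self.hd_max_mm <= 0 or self.mda_max_mm <= 0:
            raise ValueError("hd_max_mm and mda_max_mm must be > 0")


def _load_mapping(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_calibration(path) -> CalibrationConfig:
    """Read a CalibrationConfig from YAML/JSON."""
    raw = _load_mapping(path)
    table = raw.get("density_table")
    kwargs = {}
    if table is not None:
        pairs = sorted((float(h), float(d)) for h, d in table)
        kwargs["density_table"] = DensityTable(
            hu=[p[0] for p in pairs], density=[p[1] for p in pairs]
        )
    for key in ("ccf", "psf_fwhm_mm"):
        if key in raw:
            kwargs[key] = float(raw[key])
    return CalibrationConfig(**kwargs)


def load_criteria(path) -> ToleranceCriteria:
    """Read ToleranceCriteria from YAML/JSON."""
    raw = _load_mapping(path)
    return ToleranceCriteria(
        **{k: float(v) for k, v in raw.items() if k in ("dsc_min", "hd_max_mm", "mda_max_mm")}
    )
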