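"""Chronic and acute exposure dose models for the three routes.

Chronic daily doses (mg/kg·day):

* inhalation:  DD = P[mg/puff] · T · EF · ED / (BW · AT)
* oral:        DD = P[mg/ml] · CI · CF · EF · ED / (BW · AT)
* dermal:      DD = P[mg/ml] · CI · CF · SA · AF · ABS · EF · ED / (BW · AT)

Acute intake (mg/kg) for a single accidental-contact event:

* I = P[mg/ml] · AI / BW

With the default scenario (EF = 365 day/yr, ED = 70 yr, AT = 70·365 day)
the chronic time factor EF·ED/AT is exactly 1.  The dermal product
CI·SA·AF·ABS is treated as a single multiplier with CF = 1: the published
formulation is dimensionally loose, and this literal reading is the one
that reproduces every published dermal dose.  Back-solving those doses also
shows the published results used a dermal absorption fraction of 0.03 for
*all* chemicals, although the stated parameterization is 0.03 for As and
0.001 otherwise — hence two dermal modes:

* ``paper_replication`` (default): ABS = 0.03 for every chemical;
* ``as_stated``: the scenario's per-chemical ABS map (0.03 As, 0.001 rest).

Acute inhalation is deliberately not modelled: users do not inhale large
aerosol volumes in a single short event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "DERMAL_MODES",
    "ExposureScenario",
    "DoseResult",
    "dd_inhalation",
    "dd_oral",
    "dd_dermal",
    "acute_intake",
]

DERMAL_MODES = ("paper_replication", "as_stated")


@dataclass(frozen=True)
class ExposureScenario:
    """Behavioural and physiological constants of the exposure model.

    Defaults are the EPA default adult (70 kg, 20 m³/day breathing, 70-year
    duration averaged over 70·365 days), 163 puffs/day, 0.05 ml/day chronic
    e-liquid contact via leakage, and a 10 ml acute ingestion event.
    """

    bw: float = 70.0                 # body weight, kg
    t_puffs: float = 163.0           # puffs per day
    breathing_volume: float = 20.0   # m3/day (threshold-to-dose conversion only)
    ci: float = 0.05                 # chronic liquid contact, ml/day
    ai: float = 10.0                 # acute intake, ml
    ef: float = 365.0                # exposure frequency, day/year
    ed: float = 70.0                 # exposure duration, years
    at: float = 25550.0              # averaging time, days
    sa: float = 5700.0               # exposed skin area, cm2
    af: float = 0.2                  # skin adherence, mg/(cm2 day)
    cf: float = 1.0                  # unit conversion factor
    abs_default: float = 0.001       # dermal absorption fraction
    abs_by_chemical: Mapping[str, float] = field(
        default_factory=lambda: {"As": 0.03}
    )

    def __post_init__(self) -> None:
        for name in ("bw", "t_puffs", "breathing_volume", "ci", "ai", "ef",
                     "ed", "at", "sa", "af", "cf"):
            if not getattr(self, name) > 0:
                raise ValueError(f"scenario field {name} must be positive")
        if self.ef > 366:
            raise ValueError("ef cannot exceed 366 day/year")
        for chem, a in {**dict(self.abs_by_chemical), "default": self.abs_default}.items():
            if not 0 < a <= 1:
                raise ValueError(f"absorption fraction for {chem} must be in (0, 1]")

    @property
    def chronic_time_factor(self) -> float:
        """EF·ED/AT; exactly 1 for the default lifetime-averaged scenario."""
        return self.ef * self.ed / self.at

    def dermal_absorption(self, chemical: str, mode: str = "paper_replication") -> float:
        if mode not in DERMAL_MODES:
            raise ValueError(f"unknown dermal mode {mode!r}")
        if mode == "paper_replication":
            return 0.03
        return dict(self.abs_by_chemical).get(chemical, self.abs_default)

    @classmethod
    def from_dict(cls, data: Mapping) -> "ExposureScenario":
        data = dict(data)
        abs_map = data.pop("abs_by_chemical", {"As": 0.03})
        return cls(abs_by_chemical=dict(abs_map), **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExposureScenario":
        with Path(path).open(encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def paper_default(cls) -> "ExposureScenario":
        from importlib import resources

        with resources.as_file(
            resources.files("ecigrisk") / "scenarios" / "paper_default.yaml"
        ) as p:
            return cls.from_yaml(p)


@dataclass(frozen=True)
class DoseResult:
    """A per-chemical, per-route dose (mg/kg·day chronic; mg/kg acute)."""

    chemical: str | None
    route: str
    regime: str  # "chronic" | "acute"
    value: float | np.ndarray
    inputs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.regime not in ("chronic", "acute"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "acute" and self.route == "inhalation":
            raise ValueError("acute inhalation is not modelled")


def _validate_conc(p) -> float | np.ndarray:
    """Accept a scalar or array concentration; reject negatives/non-finite."""
    arr = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("concentration must be finite")
    if np.any(arr < 0):
        raise ValueError("concentration must be >= 0")
    return float(arr) if arr.ndim == 0 else arr


def dd_inhalation(
    p_ug_per_puff, s: ExposureScenario, chemical: str | None = None
) -> DoseResult:
    """Chronic inhalation daily dose from an aerosol concentration (µg/puff)."""
    p = _validate_conc(p_ug_per_puff)
    p_mg = p * 1e-3
    value = p_mg * s.t_puffs * s.ef * s.ed / (s.bw * s.at)
    return DoseResult(chemical, "inhalation", "chronic", value,
                      {"p_ug_per_puff": np.mean(p), "t_puffs": s.t_puffs, "bw": s.bw})


def dd_oral(p_mg_per_ml, s: ExposureScenario, chemical: str | None = None) -> DoseResult:
    """Chronic oral daily dose from an e-liquid concentration (mg/ml)."""
    p = _validate_conc(p_mg_per_ml)
    value = p * s.ci * s.cf * s.ef * s.ed / (s.bw * s.at)
    return DoseResult(chemical, "oral", "chronic", value,
                      {"p_mg_per_ml": np.mean(p), "ci": s.ci, "bw": s.bw})


def dd_dermal(
    p_mg_per_ml,
    chemical: str,
    s: ExposureScenario,
    mode: str = "paper_replication",
) -> DoseResult:
    """Chronic dermal daily dose from an e-liquid concentration (mg/ml)."""
    p = _validate_conc(p_mg_per_ml)
    absorption = s.dermal_absorption(chemical, mode)
    value = (
        p * s.ci * s.cf * s.sa * s.af * absorption * s.ef * s.ed / (s.bw * s.at)
    )
    return DoseResult(chemical, "dermal", "chronic", value,
                      {"p_mg_per_ml": np.mean(p), "abs": absorption, "mode_is_paper":
                       float(mode == "paper_replication")})


def acute_intake(
    p_mg_per_ml, s: ExposureScenario, chemical: str | None = None, route: str = "oral"
) -> DoseResult:
    """Acute intake (mg/kg) from a single contact with AI ml of e-liquid."""
    p = _validate_conc(p_mg_per_ml)
    value = p * s.ai / s.bw
    return DoseResult(chemical, route, "acute", value,
                      {"p_mg_per_ml": np.mean(p), "ai": s.ai, "bw": s.bw})
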