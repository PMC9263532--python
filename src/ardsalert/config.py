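"""Engine configuration: thresholds, windows, mode policy, PEEP/FiO2 grids.

Every clinically tunable constant lives here with its deployed default, so a
site can re-tune the engine from one YAML file without touching rule code.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .events import VentMode


class CpapPsLimits(BaseModel):
    """CPAP/PS is deemed inappropriate when any limit is exceeded (strict >)."""

    peep: float = 10.0  # cmH2O
    fio2: float = 0.50  # fraction
    pressure_support: float = 15.0  # cmH2O


class PeepFio2Grid(BaseModel):
    """Allowed PEEP values per FiO2 level for one co-titration strategy.

    Lookup uses the nearest grid FiO2 level not above the charted FiO2
    (falling back to the lowest level below 0.30), and a charted PEEP is
    adherent when within ``peep_tolerance`` cmH2O of any allowed value.
    """

    name: str
    allowed_pairs: dict[float, list[float]]
    peep_tolerance: float = 1.0

    @model_validator(mode="after")
    def _nonempty(self):
        if not self.allowed_pairs or any(not v for v in self.allowed_pairs.values()):
            raise ValueError("grid must map every FiO2 level to a nonempty PEEP set")
        return self

    def level_for(self, fio2: float) -> float:
        levels = sorted(self.allowed_pairs)
        at_or_below = [l for l in levels if l <= fio2 + 1e-9]
        return at_or_below[-1] if at_or_below else levels[0]

    def is_adherent(self, fio2: float, peep: float) -> bool:
        allowed = self.allowed_pairs[self.level_for(fio2)]
        return any(abs(peep - a) <= self.peep_tolerance + 1e-9 for a in allowed)


def load_default_grids() -> dict[str, PeepFio2Grid]:
    text = resources.files("ardsalert.data").joinpath("peep_fio2_grids.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: PeepFio2Grid(name=name, allowed_pairs={float(k): list(map(float, v)) for k, v in pairs.items()})
        for name, pairs in raw.items()
    }


class EngineConfig(BaseModel):
    """All engine thresholds and windows.

    Defaults reflect the deployed screening rules: altitude-adjusted
    P/F <= 255 marks qualifying hypoxemia, triggers require a ventilator
    mode charted within 7 days and intubation within 4 days of the event,
    alerts repeat at most once per 16 h per clinician, and a recommendation
    counts as followed when a consistent change lands within 120 min.
    """

    pf_threshold: float = Field(default=255.0, gt=0, description="mmHg ratio")
    barometric_pressure: float = Field(default=760.0, gt=0, description="mmHg")
    max_days_since_vent_mode_charted: float = Field(default=7.0, gt=0)
    max_days_since_intubation: float = Field(default=4.0, gt=0)
    min_age: int = Field(default=18, gt=0, description="years")
    alert_window_hours: float = Field(default=16.0, gt=0)
    adherence_window_minutes: float = Field(default=120.0, gt=0)
    vt_per_pbw_max: float = Field(default=6.5, gt=0, description="mL/kg PBW")
    peep_fio2_grid: str = "low_peep"
    cpap_ps_limits: CpapPsLimits = Field(default_factory=CpapPsLimits)
    pao2_target: tuple[float, float] = (55.0, 68.0)
    # Mode policy: `standard_modes` are recognized conventional modes;
    # `compliant_modes` are accepted by the health system's protocols; a
    # standard compliant mode that is not volume control still draws a
    # "consider volume control" suggestion.
    standard_modes: list[VentMode] = Field(
        default_factory=lambda: [
            VentMode.volume_control, VentMode.pressure_control,
            VentMode.simv, VentMode.cpap_ps,
        ]
    )
    compliant_modes: list[VentMode] = Field(
        default_factory=lambda: [
            VentMode.volume_control, VentMode.pressure_control, VentMode.cpap_ps,
        ]
    )
    grids: dict[str, PeepFio2Grid] = Field(default_factory=load_default_grids)

    @model_validator(mode="after")
    def _sane(self):
        if self.pao2_target[0] >= self.pao2_target[1]:
            raise ValueError("pao2_target lower bound must be below upper bound")
        if self.peep_fio2_grid not in self.grids:
            raise ValueError(f"unknown PEEP/FiO2 grid {self.peep_fio2_grid!r}")
        return self

    @property
    def active_grid(self) -> PeepFio2Grid:
        return self.grids[self.peep_fio2_grid]

    @classmethod
    def from_yaml(cls, path) -> "EngineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "grids" in raw:
            raw["grids"] = {
                name: {"name": name, "allowed_pairs": {float(k): v for k, v in g.items()}}
                if "allowed_pairs" not in g else g
                for name, g in raw["grids"].items()
            }
        else:
            raw["grids"] = {k: v.model_dump() for k, v in load_default_grids().items()}
        return cls.model_validate(raw)
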