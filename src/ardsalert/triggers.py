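"""Trigger detection: screening step 1 of the alert cycle.

A trigger event is raised whenever a new PaO2 is charted or a new chest
X-ray report arrives.  The trigger *fires* only when every inclusion
criterion holds (adult, ventilator mode charted within 7 days, altitude-
adjusted P/F ratio <= 255, intubated within 4 days) and no exclusion
criterion applies (PICU, palliative care, cardiothoracic attending,
mechanical circulatory support, T-piece / tracheostomy-mask breathing,
pulmonary artery catheter).  Excluded triggers are still recorded with the
full reason list for audit.

The P/F ratio pairs a PaO2 with the most recent FiO2 charted at or before
it; a radiograph trigger reuses the most recent such pair.  An altitude
adjustment scales the ratio by 760 / barometric_pressure; the default 760
applies no adjustment because the 255 threshold is already an
altitude-adjusted form of the conventional 300 mmHg cutoff.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .config import EngineConfig
from .events import (
    AirwayStatus,
    BloodGas,
    CareUnit,
    ChartEvent,
    PatientAttributes,
    RadiographReport,
)

SEA_LEVEL_PRESSURE = 760.0


class TriggerCause(str, Enum):
    new_pao2 = "new_pao2"
    new_chest_xray = "new_chest_xray"


class TriggerDecision(str, Enum):
    fired = "fired"
    excluded = "excluded"


@dataclass(frozen=True)
class DerivedPhysiology:
    """A PaO2/FiO2 pair and its (altitude-adjusted) ratio."""

    pf_ratio: float
    pf_ratio_adjusted: float
    pao2: float
    fio2: float
    source_bloodgas_time: dt.datetime
    source_fio2_time: dt.datetime


@dataclass(frozen=True)
class TriggerEvent:
    encounter_id: str
    event_id: int
    timestamp: dt.datetime
    cause: TriggerCause
    physiology: Optional[DerivedPhysiology]
    decision: TriggerDecision
    exclusion_reasons: tuple[str, ...] = ()

    @property
    def fired(self) -> bool:
        return self.decision is TriggerDecision.fired


def compute_pf_ratio(
    pao2: float,
    fio2: float,
    barometric_pressure: float = SEA_LEVEL_PRESSURE,
    *,
    bloodgas_time: Optional[dt.datetime] = None,
    fio2_time: Optional[dt.datetime] = None,
) -> DerivedPhysiology:
    """PaO2/FiO2 ratio with altitude adjustment factor 760/barometric_pressure."""
    if pao2 <= 0:
        raise ValueError(f"PaO2 must be positive, got {pao2}")
    if not (0.21 - 1e-9 <= fio2 <= 1.0 + 1e-9):
        raise ValueError(f"FiO2 must be a fraction in [0.21, 1.0], got {fio2}")
    ratio = pao2 / fio2
    return DerivedPhysiology(
        pf_ratio=ratio,
        pf_ratio_adjusted=ratio * (SEA_LEVEL_PRESSURE / barometric_pressure),
        pao2=pao2,
        fio2=fio2,
        source_bloodgas_time=bloodgas_time,
        source_fio2_time=fio2_time,
    )


def evaluate_inclusion(
    attrs: PatientAttributes,
    physiology: Optional[DerivedPhysiology],
    last_vent_mode_time: Optional[dt.datetime],
    now: dt.datetime,
    cfg: EngineConfig,
) -> list[str]:
    """Return every failed inclusion criterion (empty list = all pass).

    Day-valued windows are enforced in hours from the event timestamp
    (mode charted < 7*24 h ago, strict; intubated <= 4*24 h ago).
    """
    failed: list[str] = []
    if attrs.age < cfg.min_age:
        failed.append(f"age<{cfg.min_age}")
    if last_vent_mode_time is None:
        failed.append("vent_mode_never_charted")
    elif (now - last_vent_mode_time) >= dt.timedelta(hours=24 * cfg.max_days_since_vent_mode_charted):
        failed.append("vent_mode_stale")
    if physiology is None:
        failed.append("pf_ratio_unavailable")
    elif physiology.pf_ratio_adjusted > cfg.pf_threshold:
        failed.append("pf_ratio_above_threshold")
    if attrs.airway_status is AirwayStatus.intubated and attrs.intubation_time is None:
        failed.append("intubation_time_unknown")
    elif attrs.intubation_time is None:
        failed.append("not_recently_intubated")
    elif (now - attrs.intubation_time) > dt.timedelta(hours=24 * cfg.max_days_since_intubation):
        failed.append("intubated_over_window")
    return failed


def evaluate_exclusion(attrs: PatientAttributes) -> list[str]:
    """Return every matching exclusion criterion (empty list = not excluded)."""
    reasons: list[str] = []
    if attrs.care_unit is CareUnit.picu:
        reasons.append("picu")
    if attrs.palliative_care:
        reasons.append("palliative_care")
    if "cardiothoracic" in attrs.attending_specialty.lower():
        reasons.append("cardiothoracic_attending")
    if attrs.on_mcs:
        reasons.append("mechanical_circulatory_support")
    if attrs.airway_status in (AirwayStatus.t_piece, AirwayStatus.trach_mask):
        reasons.append("t_piece_or_trach_mask")
    if attrs.pa_catheter:
        reasons.append("pulmonary_artery_catheter")
    return reasons


@dataclass
class EncounterState:
    """Latest charted facts for one encounter, updated on every event."""

    attrs: Optional[PatientAttributes] = None
    last_fio2: Optional[float] = None
    last_fio2_time: Optional[dt.datetime] = None
    last_vent_mode_time: Optional[dt.datetime] = None
    last_settings: Optional[object] = None  # VentSettings
    last_settings_time: Optional[dt.datetime] = None
    last_physiology: Optional[DerivedPhysiology] = None
    ventilation_ordered: bool = False
    oxygenation_ordered: bool = False
    order_times: dict = field(default_factory=dict)

    def observe(self, event: ChartEvent) -> None:
        p = event.payload
        kind = p.type
        if kind == "patient_attrs":
            self.attrs = p
        elif kind == "vent_settings":
            self.last_settings = p
            self.last_settings_time = event.timestamp
            self.last_vent_mode_time = event.timestamp
            if p.fio2 is not None:
                self.last_fio2 = p.fio2
                self.last_fio2_time = event.timestamp
        elif kind == "protocol_order":
            if p.protocol == "ventilation":
                self.ventilation_ordered = True
            else:
                self.oxygenation_ordered = True
            self.order_times.setdefault(p.protocol, event.timestamp)


def process_event(
    event: ChartEvent, state: EncounterState, cfg: EngineConfig
) -> Optional[TriggerEvent]:
    """Evaluate one already-observed event for trigger generation.

    Only a new blood gas or a new radiograph report can trigger.  A blood
    gas derives fresh physiology (pairing with the latest FiO2 at or before
    it); a radiograph reuses the most recent derived physiology.  Without a
    usable PaO2/FiO2 pair no trigger is computable and nothing is emitted.
    """
    p = event.payload
    if p.type == "blood_gas":
        cause = TriggerCause.new_pao2
        if state.last_fio2 is None:
            return None
        physiology = compute_pf_ratio(
            p.pao2,
            state.last_fio2,
            cfg.barometric_pressure,
            bloodgas_time=event.timestamp,
            fio2_time=state.last_fio2_time,
        )
        state.last_physiology = physiology
    elif p.type == "radiograph_report":
        cause = TriggerCause.new_chest_xray
        physiology = state.last_physiology
        if physiology is None:
            return None
    else:
        return None

    if state.attrs is None:
        return None
    reasons = evaluate_inclusion(
        state.attrs, physiology, state.last_vent_mode_time, event.timestamp, cfg
    ) + evaluate_exclusion(state.attrs)
    return TriggerEvent(
        encounter_id=event.encounter_id,
        event_id=event.event_id,
        timestamp=event.timestamp,
        cause=cause,
        physiology=physiology,
        decision=TriggerDecision.fired if not reasons else TriggerDecision.excluded,
        exclusion_reasons=tuple(reasons),
    )
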