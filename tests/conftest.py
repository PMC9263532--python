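"""Shared fixtures: engine config and compact event-stream builders."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from ardsalert.config import EngineConfig
from ardsalert.events import (
    AirwayStatus,
    BloodGas,
    ChartClose,
    ChartEvent,
    ChartOpen,
    ClinicianResponse,
    ClinicianRole,
    PatientAttributes,
    ProtocolOrder,
    RadiographReport,
    ResponseAction,
    Sex,
    VentMode,
    VentSettings,
)

T0 = dt.datetime(2020, 3, 1, 8, 0, tzinfo=dt.timezone.utc)

POSITIVE_REPORT = "Diffuse bilateral infiltrates consistent with edema."
NEGATIVE_REPORT = "Lungs are clear. Heart size is normal."


@pytest.fixture
def cfg() -> EngineConfig:
    return EngineConfig()


def make_attrs(**overrides) -> PatientAttributes:
    base = dict(
        patient_id="P1",
        age=55,
        sex=Sex.male,
        height_cm=175.0,
        site_id="A",
        airway_status=AirwayStatus.intubated,
        intubation_time=T0,
    )
    base.update(overrides)
    return PatientAttributes(**base)


class StreamBuilder:
    """Builds an ordered encounter stream with minute offsets from T0."""

    def __init__(self, encounter_id: str = "E1", t0: dt.datetime = T0):
        self.encounter_id = encounter_id
        self.t0 = t0
        self.events: list[ChartEvent] = []

    def at(self, minutes: float, payload) -> "StreamBuilder":
        self.events.append(
            ChartEvent(
                encounter_id=self.encounter_id,
                event_id=len(self.events) + 1,
                timestamp=self.t0 + dt.timedelta(minutes=minutes),
                payload=payload,
            )
        )
        return self

    def build(self) -> list[ChartEvent]:
        return list(self.events)


@pytest.fixture
def stream() -> StreamBuilder:
    return StreamBuilder()


def random_stream(rng: np.random.Generator, max_events: int = 40) -> list[ChartEvent]:
    """A randomized but schema-valid encounter stream for property tests.

    Mixes every payload kind, multiple clinicians, occasional suppressing
    responses, and time steps up to ~7 h so the 16-h alert window and the
    staleness windows are both exercised.
    """
    b = StreamBuilder("R1")
    minutes = 0.0
    b.at(0.0, make_attrs(pa_catheter=bool(rng.random() < 0.05)))
    clinicians = ["MD1", "MD2", "MD3"]
    n = int(rng.integers(3, max_events))
    for _ in range(n):
        minutes += float(rng.uniform(1, 420))
        kind = rng.random()
        if kind < 0.22:
            b.at(minutes, BloodGas(pao2=float(rng.uniform(40, 400))))
        elif kind < 0.40:
            b.at(minutes, VentSettings(
                mode=VentMode(list(VentMode)[int(rng.integers(len(VentMode)))]),
                tidal_volume=float(rng.uniform(250, 700)),
                peep=float(rng.integers(0, 20)),
                fio2=float(rng.uniform(0.21, 1.0)),
                pressure_support=float(rng.integers(0, 22)),
            ))
        elif kind < 0.52:
            text = POSITIVE_REPORT if rng.random() < 0.6 else NEGATIVE_REPORT
            b.at(minutes, RadiographReport(report_text=text))
        elif kind < 0.60:
            b.at(minutes, ProtocolOrder(
                protocol="ventilation" if rng.random() < 0.5 else "oxygenation"))
        elif kind < 0.78:
            b.at(minutes, ChartOpen(
                clinician_id=clinicians[int(rng.integers(3))],
                role=ClinicianRole.physician if rng.random() < 0.8
                else ClinicianRole.respiratory_therapist,
            ))
        elif kind < 0.92:
            b.at(minutes, ChartClose(clinician_id=clinicians[int(rng.integers(3))]))
        else:
            b.at(minutes, ClinicianResponse(
                clinician_id=clinicians[int(rng.integers(3))],
                action=ResponseAction.not_ards if rng.random() < 0.3
                else ResponseAction.act_on_instruction,
            ))
    return b.build()
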