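"""Event-stream domain model.

One ICU encounter is a strictly ordered sequence of :class:`ChartEvent`
records: charted arterial blood gases, ventilator settings, chest-radiograph
report text, protocol orders, chart open/close actions and clinician
responses to alerts.  The engine consumes exactly this stream — no other
channel exists — which mirrors how an EHR rules engine sees patient care.

Streams are serialized as JSONL (one event per line, canonical field order,
ISO-8601 UTC timestamps) or an equivalent long-format CSV.  Parsing is
strict: malformed records raise :class:`StreamParseError` naming the line.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from enum import Enum
from typing import Annotated, Iterable, Literal, Optional, TextIO, Union

from pydantic import BaseModel, Field, ValidationError, field_validator

SCHEMA_VERSION = "1"

AMBIENT_FIO2 = 0.21


class StreamParseError(ValueError):
    """A malformed record in an event stream; carries the 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class StreamValidationError(ValueError):
    """A record parsed but violated a domain invariant."""


def normalize_fio2(raw: float) -> float:
    """Normalize a charted FiO2 to a fraction in [0.21, 1.0].

    EHR exports chart FiO2 in two dialects: a fraction (0.40) or a percent
    (40).  Values above 1 are interpreted as percent and divided by 100.
    Values outside [0.21, 1.0] after normalization are rejected — below
    ambient air is physically impossible on a ventilator.
    """
    if raw <= 0:
        raise StreamValidationError(f"FiO2 must be positive, got {raw!r}")
    value = raw / 100.0 if raw > 1.0 else float(raw)
    if not (AMBIENT_FIO2 - 1e-9 <= value <= 1.0 + 1e-9):
        raise StreamValidationError(
            f"FiO2 {raw!r} normalizes to {value:g}, outside [0.21, 1.0]"
        )
    return min(max(value, AMBIENT_FIO2), 1.0)


class Sex(str, Enum):
    male = "male"
    female = "female"


class CareUnit(str, Enum):
    adult_icu = "adult_icu"
    picu = "picu"
    other = "other"


class AirwayStatus(str, Enum):
    intubated = "intubated"
    t_piece = "t_piece"
    trach_mask = "trach_mask"
    extubated = "extubated"


class VentMode(str, Enum):
    """Ventilator modes, grouped by the engine's mode-compliance config."""

    volume_control = "volume_control"
    pressure_control = "pressure_control"
    simv = "simv"
    cpap_ps = "cpap_ps"
    aprv = "aprv"
    hfov = "hfov"
    other = "other"


class ClinicianRole(str, Enum):
    physician = "physician"
    app = "app"  # advanced practice provider
    nurse = "nurse"
    respiratory_therapist = "respiratory_therapist"


class ResponseAction(str, Enum):
    order_protocol = "order_protocol"
    act_on_instruction = "act_on_instruction"
    not_ards = "not_ards"
    contraindication = "contraindication"


class ContraindicationReason(str, Enum):
    elevated_icp = "elevated_icp"
    status_asthmaticus = "status_asthmaticus"
    severe_copd = "severe_copd"
    other = "other"


class PatientAttributes(BaseModel):
    """Demographic / admission metadata used by inclusion-exclusion logic."""

    type: Literal["patient_attrs"] = "patient_attrs"
    patient_id: str
    age: int = Field(ge=0)
    sex: Optional[Sex] = None
    height_cm: Optional[float] = Field(default=None, gt=0)
    care_unit: CareUnit = CareUnit.adult_icu
    site_id: Optional[str] = None
    palliative_care: bool = False
    attending_specialty: str = ""
    on_mcs: bool = False
    pa_catheter: bool = False
    airway_status: AirwayStatus = AirwayStatus.intubated
    intubation_time: Optional[dt.datetime] = None


class BloodGas(BaseModel):
    type: Literal["blood_gas"] = "blood_gas"
    pao2: float = Field(gt=0, description="arterial O2 partial pressure, mmHg")


class VentSettings(BaseModel):
    type: Literal["vent_settings"] = "vent_settings"
    mode: VentMode
    tidal_volume: Optional[float] = Field(default=None, ge=0, description="mL")
    peep: Optional[float] = Field(default=None, ge=0, description="cmH2O")
    fio2: Optional[float] = None
    pressure_support: Optional[float] = Field(default=None, ge=0, description="cmH2O")

    @field_validator("fio2")
    @classmethod
    def _norm_fio2(cls, v):
        return None if v is None else normalize_fio2(v)


class RadiographReport(BaseModel):
    type: Literal["radiograph_report"] = "radiograph_report"
    report_text: str = ""


class ProtocolOrder(BaseModel):
    type: Literal["protocol_order"] = "protocol_order"
    protocol: Literal["ventilation", "oxygenation"]


class ChartOpen(BaseModel):
    type: Literal["chart_open"] = "chart_open"
    clinician_id: str
    role: ClinicianRole = ClinicianRole.physician


class ChartClose(BaseModel):
    type: Literal["chart_close"] = "chart_close"
    clinician_id: str


class ClinicianResponse(BaseModel):
    type: Literal["clinician_response"] = "clinician_response"
    clinician_id: str
    action: ResponseAction
    reason: Optional[ContraindicationReason] = None
    reason_text: Optional[str] = None

    @field_validator("reason_text")
    @classmethod
    def _other_needs_text(cls, v, info):
        if info.data.get("reason") == ContraindicationReason.other and not (v or "").strip():
            raise ValueError("contraindication reason 'other' requires free text")
        return v


Payload = Annotated[
    Union[
        PatientAttributes,
        BloodGas,
        VentSettings,
        RadiographReport,
        ProtocolOrder,
        ChartOpen,
        ChartClose,
        ClinicianResponse,
    ],
    Field(discriminator="type"),
]

PAYLOAD_TYPES = {
    "patient_attrs": PatientAttributes,
    "blood_gas": BloodGas,
    "vent_settings": VentSettings,
    "radiograph_report": RadiographReport,
    "protocol_order": ProtocolOrder,
    "chart_open": ChartOpen,
    "chart_close": ChartClose,
    "clinician_response": ClinicianResponse,
}


class ChartEvent(BaseModel):
    """One timestamped charting fact within an encounter.

    ``(timestamp, event_id)`` gives a strict total order within an encounter;
    the engine is a single pass over that order.
    """

    encounter_id: str
    event_id: int
    timestamp: dt.datetime
    payload: Payload

    @field_validator("timestamp")
    @classmethod
    def _tz_aware_utc(cls, v: dt.datetime) -> dt.datetime:
        if v.tzinfo is None:
            raise ValueError("timestamp must carry an explicit UTC offset")
        return v.astimezone(dt.timezone.utc)

    def sort_key(self):
        return (self.timestamp, self.event_id)


def _iso_utc(t: dt.datetime) -> str:
    return t.astimezone(dt.timezone.utc).isoformat().replace("+00:00", "Z")


def event_to_json(event: ChartEvent) -> str:
    """Render one event as its canonical JSONL line (fixed field order)."""
    payload = event.payload.model_dump(exclude_none=True, mode="json")
    if isinstance(event.payload, PatientAttributes) and event.payload.intubation_time:
        payload["intubation_time"] = _iso_utc(event.payload.intubation_time)
    doc = {
        "schema": SCHEMA_VERSION,
        "encounter_id": event.encounter_id,
        "event_id": event.event_id,
        "timestamp": _iso_utc(event.timestamp),
        "payload": payload,
    }
    return json.dumps(doc, separators=(", ", ": "), ensure_ascii=False)


def parse_event_stream(source: Union[Iterable[str], TextIO]) -> dict[str, list[ChartEvent]]:
    """Parse a JSONL event stream into per-encounter ordered event lists.

    Events are sorted by ``(timestamp, event_id)`` regardless of input record
    order; a duplicated ``event_id`` within an encounter is rejected, as is
    any record whose payload tag or field values fail validation.  Encounters
    are returned keyed by ``encounter_id`` in sorted key order.
    """
    encounters: dict[str, list[ChartEvent]] = {}
    seen_ids: dict[str, set[int]] = {}
    for lineno, line in enumerate(source, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            doc = json.loads(line)
        except json.JSONDecodeError as exc:
            raise StreamParseError(f"invalid JSON: {exc}", lineno) from exc
        if not isinstance(doc, dict):
            raise StreamParseError("record is not a JSON object", lineno)
        ptype = (doc.get("payload") or {}).get("type")
        if ptype not in PAYLOAD_TYPES:
            raise StreamParseError(f"unknown payload tag {ptype!r}", lineno)
        try:
            event = ChartEvent.model_validate(
                {k: doc[k] for k in ("encounter_id", "event_id", "timestamp", "payload")}
            )
        except (KeyError, ValidationError) as exc:
            raise StreamParseError(f"invalid record: {exc}", lineno) from exc
        ids = seen_ids.setdefault(event.encounter_id, set())
        if event.event_id in ids:
            raise StreamParseError(
                f"duplicate event_id {event.event_id} in encounter {event.encounter_id}",
                lineno,
            )
        ids.add(event.event_id)
        encounters.setdefault(event.encounter_id, []).append(event)
    return {
        enc: sorted(evts, key=ChartEvent.sort_key)
        for enc, evts in sorted(encounters.items())
    }


def write_event_stream(encounters: dict[str, list[ChartEvent]], out: TextIO) -> None:
    """Write encounters as the canonical JSONL stream (idempotent round-trip)."""
    for enc in sorted(encounters):
        for event in sorted(encounters[enc], key=ChartEvent.sort_key):
            out.write(event_to_json(event) + "\n")


_CSV_COLUMNS = [
    "encounter_id", "event_id", "timestamp", "type",
    "pao2", "mode", "tidal_volume", "peep", "fio2", "pressure_support",
    "report_text", "protocol", "clinician_id", "role", "action", "reason",
    "reason_text", "patient_id", "age", "sex", "height_cm", "care_unit",
    "site_id", "palliative_care", "attending_specialty", "on_mcs",
    "pa_catheter", "airway_status", "intubation_time",
]


def write_event_stream_csv(encounters: dict[str, list[ChartEvent]], out: TextIO) -> None:
    """Long-format CSV equivalent of the JSONL stream (same column set always)."""
    writer = csv.DictWriter(out, fieldnames=_CSV_COLUMNS, lineterminator="\n")
    writer.writeheader()
    for enc in sorted(encounters):
        for event in sorted(encounters[enc], key=ChartEvent.sort_key):
            row = {c: "" for c in _CSV_COLUMNS}
            row.update(
                encounter_id=event.encounter_id,
                event_id=event.event_id,
                timestamp=_iso_utc(event.timestamp),
            )
            payload = event.payload.model_dump(exclude_none=True, mode="json")
            for key, value in payload.items():
                if key == "intubation_time" and event.payload.intubation_time:  # type: ignore[union-attr]
                    value = _iso_utc(event.payload.intubation_time)  # type: ignore[union-attr]
                row[key] = value
            writer.writerow(row)


def read_event_stream_csv(source: TextIO) -> dict[str, list[ChartEvent]]:
    """Parse the long-format CSV dialect back into per-encounter events."""
    reader = csv.DictReader(source)
    lines = []
    for i, row in enumerate(reader, start=2):
        ptype = row.get("type", "")
        if ptype not in PAYLOAD_TYPES:
            raise StreamParseError(f"unknown payload tag {ptype!r}", i)
        fields = set(PAYLOAD_TYPES[ptype].model_fields)
        payload = {k: v for k, v in row.items() if k in fields and v != ""}
        payload["type"] = ptype
        doc = {
            "schema": SCHEMA_VERSION,
            "encounter_id": row["encounter_id"],
            "event_id": int(row["event_id"]),
            "timestamp": row["timestamp"],
            "payload": payload,
        }
        lines.append(json.dumps(doc))
    return parse_event_stream(lines)
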