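"""Single-pass alert engine: trigger -> detection -> adherence -> alert.

One evaluation cycle per charting event, in stream order: a new blood gas
or radiograph raises a trigger; a fired trigger is screened for bilateral
infiltrates; a positive screen has its current treatment checked against
the ventilation/oxygenation protocols; a nonadherent result becomes the
pending alert, delivered on the next eligible chart open.  New biomedical
data re-evokes the cycle; an adherent re-evaluation clears the pending
alert; suppressing clinician responses end alerting for the encounter.

The engine's outputs are append-only ledgers (triggers, possible-ARDS
events, alerts, reminders, responses) that downstream service metrics
consume — the same audit surface the production tool exposes.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

from .adherence import PossibleARDSEvent, assess_lpv
from .alerts import (
    Alert,
    Reminder,
    SuppressionState,
    deliver_on_chart_open,
    record_response,
    remind_on_chart_close,
)
from .config import EngineConfig
from .events import ChartEvent
from .infiltrates import DetectionResult, InfiltrateClassifier, RuleBasedDetector
from .triggers import EncounterState, TriggerEvent, process_event


@dataclass
class _ChartSession:
    clinician_id: str
    opened_at: dt.datetime
    alerts: list[Alert] = field(default_factory=list)
    payloads: list = field(default_factory=list)


@dataclass
class EncounterLedger:
    """Everything the engine recorded for one encounter."""

    encounter_id: str
    events: list[ChartEvent] = field(default_factory=list)
    triggers: list[TriggerEvent] = field(default_factory=list)
    possible_events: list[PossibleARDSEvent] = field(default_factory=list)
    alerts: list[Alert] = field(default_factory=list)
    reminders: list[Reminder] = field(default_factory=list)
    responses: list[tuple[dt.datetime, object]] = field(default_factory=list)
    suppression: SuppressionState = field(default_factory=SuppressionState)
    site_id: Optional[str] = None

    @property
    def fired_triggers(self) -> list[TriggerEvent]:
        return [t for t in self.triggers if t.fired]

    @property
    def nonadherent_events(self) -> list[PossibleARDSEvent]:
        return [e for e in self.possible_events if not e.lpv_adherent]


class AlertEngine:
    """Replays an encounter event stream through the full alert cycle."""

    def __init__(
        self,
        cfg: Optional[EngineConfig] = None,
        detector: Optional[InfiltrateClassifier] = None,
    ):
        self.cfg = cfg or EngineConfig()
        self.detector = detector or RuleBasedDetector()

    def run_encounter(self, events: list[ChartEvent]) -> EncounterLedger:
        cfg = self.cfg
        events = sorted(events, key=ChartEvent.sort_key)
        ledger = EncounterLedger(encounter_id=events[0].encounter_id if events else "")
        state = EncounterState()
        last_detection: Optional[DetectionResult] = None
        pending: Optional[PossibleARDSEvent] = None
        sessions: dict[str, _ChartSession] = {}
        alert_seq = 0

        for event in events:
            p = event.payload
            state.observe(event)
            if p.type == "patient_attrs" and ledger.site_id is None:
                ledger.site_id = p.site_id

            # feed non-UI payloads to open chart sessions (addressed-check surface)
            if p.type in ("vent_settings", "protocol_order", "clinician_response"):
                for session in sessions.values():
                    session.payloads.append(p)

            if p.type == "radiograph_report":
                last_detection = self.detector(p)

            trigger = process_event(event, state, cfg)
            if trigger is not None:
                ledger.triggers.append(trigger)
                if trigger.fired and last_detection is not None:
                    pae = assess_lpv(trigger, last_detection, state, cfg)
                    if pae is not None:
                        ledger.possible_events.append(pae)
                        # a fresh nonadherent result becomes the pending
                        # alert; an adherent re-evaluation clears it
                        pending = pae if not pae.lpv_adherent else None

            if p.type == "chart_open":
                session = _ChartSession(p.clinician_id, event.timestamp)
                sessions[p.clinician_id] = session
                alert_seq += 1
                alert = deliver_on_chart_open(
                    p, event.timestamp, event.encounter_id, pending,
                    ledger.suppression, cfg,
                    alert_id=f"{event.encounter_id}-a{alert_seq}",
                )
                if alert is not None:
                    ledger.alerts.append(alert)
                    session.alerts.append(alert)
            elif p.type == "chart_close":
                session = sessions.pop(p.clinician_id, None)
                if session is not None:
                    for alert in session.alerts:
                        reminder = remind_on_chart_close(
                            alert, session.payloads, event.timestamp, cfg
                        )
                        if reminder is not None:
                            ledger.reminders.append(reminder)
            elif p.type == "clinician_response":
                ledger.responses.append((event.timestamp, p))
                if ledger.alerts:  # a response must reference a delivered alert
                    record_response(p, ledger.suppression)

        ledger.events = events
        return ledger

    def run_stream(self, encounters: dict[str, list[ChartEvent]]) -> dict[str, EncounterLedger]:
        """Run every encounter independently; encounters share no state."""
        return {enc: self.run_encounter(evts) for enc, evts in encounters.items()}
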