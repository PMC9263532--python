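"""Alert lifecycle: delivery, reminders, rate limiting and suppression.

Alerts are synchronous: a pending nonadherent possible-ARDS event is shown
to a treating physician or advanced practice provider when they open the
patient chart, at most once per 16 h per clinician (rolling window from the
last delivery).  If any recommendation remains unaddressed when the chart
closes, the clinician is reminded once.  A "not ARDS" or contraindication
response permanently suppresses all future alerts for the patient — the
suppression is absorbing for the remainder of the encounter.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

from .adherence import PossibleARDSEvent, Recommendation, resolves
from .config import EngineConfig
from .events import ChartOpen, ClinicianResponse, ClinicianRole, ResponseAction

ALERT_ELIGIBLE_ROLES = frozenset({ClinicianRole.physician, ClinicianRole.app})


@dataclass
class Alert:
    """One delivered alert message bundling >=1 recommendations."""

    alert_id: str
    encounter_id: str
    clinician_id: str
    created_at: dt.datetime  # nonadherent event time
    delivered_at: dt.datetime  # chart-open time
    recommendations: tuple[Recommendation, ...]
    reminder_delivered: bool = False

    def __post_init__(self):
        if not self.recommendations:
            raise ValueError("an alert must carry at least one recommendation")
        if self.delivered_at < self.created_at:
            raise ValueError("delivered_at precedes created_at")


@dataclass
class Reminder:
    alert_id: str
    clinician_id: str
    timestamp: dt.datetime
    unaddressed: tuple[Recommendation, ...]


@dataclass
class SuppressionState:
    """Per-patient alert-eligibility bookkeeping.

    ``permanent_suppressed`` is absorbing: once a clinician marks the
    patient not-ARDS or contraindicated, it never reverts within the
    encounter.  ``last_alert_time`` is tracked per clinician.
    """

    permanent_suppressed: bool = False
    suppression_cause: Optional[str] = None
    last_alert_time: dict[str, dt.datetime] = field(default_factory=dict)

    def suppress(self, cause: str) -> None:
        self.permanent_suppressed = True
        if self.suppression_cause is None:
            self.suppression_cause = cause


def should_deliver(
    state: SuppressionState, clinician_id: str, now: dt.datetime, cfg: EngineConfig
) -> tuple[bool, str]:
    """Whether an alert may be delivered to this clinician right now."""
    if state.permanent_suppressed:
        return False, f"permanently_suppressed:{state.suppression_cause}"
    last = state.last_alert_time.get(clinician_id)
    if last is not None and (now - last) < dt.timedelta(hours=cfg.alert_window_hours):
        return False, "within_16h_window"
    return True, "eligible"


def deliver_on_chart_open(
    open_event: ChartOpen,
    now: dt.datetime,
    encounter_id: str,
    pending: Optional[PossibleARDSEvent],
    state: SuppressionState,
    cfg: EngineConfig,
    alert_id: str,
) -> Optional[Alert]:
    """Deliver the pending nonadherent event as an alert, if eligible.

    Chart opens by roles other than physician/APP never deliver; the
    per-clinician window timestamp updates atomically with delivery.
    """
    if pending is None or pending.lpv_adherent:
        return None
    if open_event.role not in ALERT_ELIGIBLE_ROLES:
        return None
    ok, _reason = should_deliver(state, open_event.clinician_id, now, cfg)
    if not ok:
        return None
    state.last_alert_time[open_event.clinician_id] = now
    return Alert(
        alert_id=alert_id,
        encounter_id=encounter_id,
        clinician_id=open_event.clinician_id,
        created_at=pending.trigger.timestamp,
        delivered_at=now,
        recommendations=pending.recommendations,
    )


def remind_on_chart_close(
    alert: Alert,
    session_payloads: list,
    close_time: dt.datetime,
    cfg: EngineConfig,
) -> Optional[Reminder]:
    """Issue a close-of-chart reminder when recommendations went unaddressed.

    A recommendation is addressed when, between chart open and close, the
    clinician responded to the alert or a charted change consistent with
    the recommendation occurred (same consistency rule as the followed
    metric).  At most one reminder per alert.
    """
    if alert.reminder_delivered:
        return None
    responded = any(p.type == "clinician_response" for p in session_payloads)
    unaddressed = []
    for rec in alert.recommendations:
        if responded:
            continue
        orders_state: dict = {}
        if not any(resolves(rec, p, cfg, orders_state=orders_state) for p in session_payloads):
            unaddressed.append(rec)
    if not unaddressed:
        return None
    alert.reminder_delivered = True
    return Reminder(
        alert_id=alert.alert_id,
        clinician_id=alert.clinician_id,
        timestamp=close_time,
        unaddressed=tuple(unaddressed),
    )


def record_response(resp: ClinicianResponse, state: SuppressionState) -> SuppressionState:
    """Apply a clinician response to the suppression state.

    not_ards and contraindication responses permanently suppress alerts for
    the patient; ordering a protocol or acting on an instruction never does.
    """
    if resp.action is ResponseAction.not_ards:
        state.suppress("not_ards")
    elif resp.action is ResponseAction.contraindication:
        reason = resp.reason.value if resp.reason else "unspecified"
        state.suppress(f"contraindication:{reason}")
    return state
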