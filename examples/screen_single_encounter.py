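"""Walk one encounter through the screening pipeline step by step.

Builds a small charting sequence (admission, ventilator settings, a chest
film, a blood gas, a chart open), runs the alert engine over it, and prints
each trigger decision, the possible-ARDS assessment, and the delivered
alert.  The printed P/F ratio is PaO2/FiO2 in mmHg; values at or below 255
qualify as possible-ARDS hypoxemia.
"""

import datetime as dt

from ardsalert import AlertEngine, ChartEvent, EngineConfig
from ardsalert.events import (
    BloodGas, ChartOpen, ClinicianRole, PatientAttributes, RadiographReport,
    Sex, VentMode, VentSettings,
)

T0 = dt.datetime(2020, 3, 1, 8, 0, tzinfo=dt.timezone.utc)


def at(minutes, event_id, payload):
    return ChartEvent(encounter_id="DEMO", event_id=event_id,
                      timestamp=T0 + dt.timedelta(minutes=minutes), payload=payload)


events = [
    at(0, 1, PatientAttributes(patient_id="P1", age=61, sex=Sex.male, height_cm=178,
                               intubation_time=T0)),
    # volume control but tidal volume 560 mL on a ~73 kg predicted body weight
    at(30, 2, VentSettings(mode=VentMode.volume_control, tidal_volume=560,
                           peep=5, fio2=0.70, pressure_support=0)),
    at(45, 3, RadiographReport(report_text="Diffuse bilateral infiltrates consistent with edema.")),
    at(60, 4, BloodGas(pao2=84)),          # P/F = 84/0.70 = 120 -> qualifies
    at(75, 5, ChartOpen(clinician_id="MD1", role=ClinicianRole.physician)),
]

ledger = AlertEngine(EngineConfig()).run_encounter(events)

for trig in ledger.triggers:
    pf = trig.physiology.pf_ratio_adjusted if trig.physiology else None
    print(f"trigger {trig.cause.value:14s} decision={trig.decision.value:8s} "
          f"adjusted P/F={pf and round(pf, 1)} reasons={list(trig.exclusion_reasons)}")

for event in ledger.possible_events:
    print(f"possible ARDS event: LPV adherent={event.lpv_adherent}")
    for rec in event.recommendations:
        print(f"  recommendation: {rec.rec_type.value} ({rec.category.value})  "
              f"evidence={rec.evidence}")

for alert in ledger.alerts:
    print(f"alert to {alert.clinician_id} at {alert.delivered_at:%H:%M} with "
          f"{len(alert.recommendations)} recommendation(s)")
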