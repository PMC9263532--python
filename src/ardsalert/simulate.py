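"""Seeded synthetic ICU encounter streams with planted ground truth.

The generator emulates the charting surface the alert engine consumes —
admission metadata, ventilator settings, arterial blood gases, radiograph
report text, protocol orders, chart opens/closes and clinician responses —
with planted encounter-level labels: whether the encounter develops a
possible-ARDS picture, whether its treatment is initially nonadherent, and
whether each alert recommendation is followed within the adherence window.

Planted labels go to a ground-truth sidecar that the engine never reads;
the engine sees only the event stream, exactly as the production tool saw
only the EHR.  ``p_possible_ards`` and ``p_nonadherent`` are *marginal*
per-encounter rates among trigger-bearing encounters, so the engine's
measured initial nonadherence estimates ``p_nonadherent`` directly.

Values are sampled to satisfy or violate the screening thresholds, not to
be physiologically realistic trajectories: every encounter carries at least
one qualifying (P/F <= 255) blood gas so it enters the study denominator,
and radiograph text is drawn from the same templated language families as
the classifier's validation corpus.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .events import (
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

_EPOCH = dt.datetime(2020, 1, 1, tzinfo=dt.timezone.utc)

REPORT_TEMPLATES: dict[str, list[str]] = {
    "bilateral_pos": [
        "Diffuse bilateral infiltrates consistent with edema.",
        "Bilateral patchy airspace opacities are present.",
        "Worsening bilateral consolidation in the lower lobes.",
        "There are bibasilar opacities, likely atelectasis versus pneumonia.",
        "Extensive airspace disease involving both lungs.",
        "Patchy opacities in the right and left lower lobes.",
        "Dense consolidations are seen bilaterally at the bases.",
        "Bilateral perihilar opacities suggest pulmonary edema.",
    ],
    "uncertain": [
        "Possible bilateral infiltrates, correlate clinically.",
        "Findings may represent bilateral airspace disease.",
        "Cannot exclude early bilateral consolidation.",
        "Hazy bilateral opacities, possibly edema.",
        "Concerning for bilateral opacities superimposed on chronic changes.",
    ],
    "negated": [
        "No bilateral infiltrates are identified.",
        "No focal infiltrate; lungs clear bilaterally.",
        "Lungs are clear without bilateral opacities.",
        "Interval resolution of bilateral infiltrates.",
        "No new bilateral opacities; stable cardiomegaly.",
    ],
    "clear": [
        "Lungs are clear. Heart size is normal.",
        "No acute cardiopulmonary process.",
        "Clear lungs with normal cardiomediastinal silhouette.",
        "Right lower lobe atelectasis; otherwise unremarkable.",
        "Stable cardiomegaly. No pleural effusion.",
    ],
}

_NEUTRAL_SENTENCES = [
    "Endotracheal tube in standard position.",
    "Lines and tubes are unchanged.",
    "Heart size is stable.",
    "Degenerative changes of the thoracic spine.",
]


class CohortSpec(BaseModel):
    """Parameters of a synthetic cohort.

    The default planted rates mirror the deployed tool's observed study
    conditions: 38% of trigger-bearing encounters initially nonadherent,
    65% of specific-setting recommendations followed, 14% of
    protocol-adoption recommendations followed.
    """

    n_encounters: int = Field(ge=1)
    seed: int = 0
    p_possible_ards: float = Field(default=0.60, ge=0.0, le=1.0)
    p_nonadherent: float = Field(default=0.38, ge=0.0, le=1.0)
    p_follow_adopt: float = Field(default=0.14, ge=0.0, le=1.0)
    p_follow_specific: float = Field(default=0.65, ge=0.0, le=1.0)
    p_response: float = Field(default=0.10, ge=0.0, le=1.0)
    p_suppressing_response: float = Field(default=0.03, ge=0.0, le=1.0)
    mean_triggers_per_encounter: float = Field(default=1.5, gt=0.0)
    site_distribution: dict[str, float] = Field(
        default_factory=lambda: {"A": 0.34, "B": 0.23, "C": 0.21, "D": 0.14, "E": 0.05, "F": 0.03}
    )
    report_templates: dict[str, list[str]] = Field(
        default_factory=lambda: {k: list(v) for k, v in REPORT_TEMPLATES.items()}
    )

    @model_validator(mode="after")
    def _coherent(self):
        if self.p_nonadherent > self.p_possible_ards + 1e-12:
            raise ValueError("p_nonadherent cannot exceed p_possible_ards (both are marginal rates)")
        if not self.site_distribution or any(w < 0 for w in self.site_distribution.values()):
            raise ValueError("site_distribution must be nonempty with nonnegative weights")
        for label in ("bilateral_pos", "uncertain", "negated", "clear"):
            if not self.report_templates.get(label):
                raise ValueError(f"report_templates must cover label {label!r}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Sidecar record of what was planted for one encounter."""

    encounter_id: str
    site_id: str
    possible_ards: bool
    nonadherent: bool
    scenario: str
    report_labels: list[str]
    planted_follow: Optional[bool]
    rec_category: Optional[str]

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def render_report(label: str, rng: np.random.Generator,
                  templates: Optional[dict[str, list[str]]] = None) -> RadiographReport:
    """Draw report text for a planted label, with lexical jitter."""
    templates = templates or REPORT_TEMPLATES
    text = templates[label][int(rng.integers(len(templates[label])))]
    if rng.random() < 0.5:
        extra = _NEUTRAL_SENTENCES[int(rng.integers(len(_NEUTRAL_SENTENCES)))]
        text = f"{extra} {text}" if rng.random() < 0.5 else f"{text} {extra}"
    return RadiographReport(report_text=text)


def _pbw(sex: Sex, height_cm: float) -> float:
    return (50.0 if sex is Sex.male else 45.5) + 0.91 * (height_cm - 152.4)


class _EncounterBuilder:
    def __init__(self, encounter_id: str, t0: dt.datetime):
        self.encounter_id = encounter_id
        self.t0 = t0
        self.events: list[ChartEvent] = []
        self._next_id = 1

    def add(self, minutes: float, payload) -> ChartEvent:
        event = ChartEvent(
            encounter_id=self.encounter_id,
            event_id=self._next_id,
            timestamp=self.t0 + dt.timedelta(minutes=float(minutes)),
            payload=payload,
        )
        self._next_id += 1
        self.events.append(event)
        return event


_ADOPT_SCENARIOS = ("both_protocols_missing", "ventilation_missing", "oxygenation_missing", "cpap_breach")


def _generate_encounter(
    spec: CohortSpec, rng: np.random.Generator, index: int
) -> tuple[list[ChartEvent], GroundTruth]:
    enc_id = f"E{index + 1:05d}"
    t0 = _EPOCH + dt.timedelta(hours=6 * index)
    b = _EncounterBuilder(enc_id, t0)

    sites = sorted(spec.site_distribution)
    weights = np.array([spec.site_distribution[s] for s in sites], dtype=float)
    site = sites[int(rng.choice(len(sites), p=weights / weights.sum()))]

    sex = Sex.male if rng.random() < 0.55 else Sex.female
    height = float(rng.uniform(152, 195))
    pbw = _pbw(sex, height)
    attrs = PatientAttributes(
        patient_id=f"P{index + 1:05d}",
        age=int(rng.integers(25, 86)),
        sex=sex,
        height_cm=round(height, 1),
        site_id=site,
        airway_status=AirwayStatus.intubated,
        intubation_time=t0,
    )
    b.add(0, attrs)

    u = rng.random()
    if u < spec.p_nonadherent:
        kind = "nonadherent"
    elif u < spec.p_possible_ards:
        kind = "adherent_ards"
    else:
        kind = "no_ards"

    adherent_settings = dict(
        mode=VentMode.volume_control,
        tidal_volume=round(6.0 * pbw, 0),
        peep=10.0,
        fio2=0.60,
        pressure_support=0.0,
    )
    report_labels: list[str] = []
    planted_follow: Optional[bool] = None
    rec_category: Optional[str] = None
    scenario = kind

    charted_fio2 = {"value": 0.60}

    def qualifying_pao2() -> float:
        # P/F in ~[100, 230] at the charted FiO2 -> always below the threshold
        return round(charted_fio2["value"] * float(rng.uniform(100, 230)), 1)

    def pos_label() -> str:
        return "bilateral_pos" if rng.random() < 0.7 else "uncertain"

    def neg_label() -> str:
        return "clear" if rng.random() < 0.6 else "negated"

    if kind in ("adherent_ards", "no_ards"):
        b.add(30, VentSettings(**adherent_settings))
        b.add(40, ProtocolOrder(protocol="ventilation"))
        b.add(42, ProtocolOrder(protocol="oxygenation"))
        label = pos_label() if kind == "adherent_ards" else neg_label()
        report_labels.append(label)
        b.add(55, render_report(label, rng, spec.report_templates))
        b.add(60, BloodGas(pao2=qualifying_pao2()))
        b.add(70 + rng.uniform(0, 20), ChartOpen(clinician_id=f"MD{index % 97:03d}",
                                                 role=ClinicianRole.physician))
        b.add(100 + rng.uniform(0, 20), ChartClose(clinician_id=f"MD{index % 97:03d}"))
    else:
        # nonadherent: alternate between protocol-adoption gaps and
        # specific-setting gaps so both follow rates are exercised
        specific = rng.random() < 0.5
        rec_category = "specific_setting" if specific else "adopt_protocol"
        if specific:
            scenario = "specific_peep_fio2" if rng.random() < 0.7 else "specific_peep_and_vt"
            b.add(30, ProtocolOrder(protocol="ventilation"))
            b.add(32, ProtocolOrder(protocol="oxygenation"))
            bad = dict(adherent_settings)
            bad.update(peep=6.0, fio2=0.80)  # off-grid pair at FiO2 0.80
            if scenario == "specific_peep_and_vt":
                bad["tidal_volume"] = round(8.5 * pbw, 0)
            b.add(35, VentSettings(**bad))
            charted_fio2["value"] = 0.80
        else:
            scenario = _ADOPT_SCENARIOS[int(rng.integers(len(_ADOPT_SCENARIOS)))]
            if scenario == "ventilation_missing":
                b.add(30, ProtocolOrder(protocol="oxygenation"))
                b.add(35, VentSettings(**adherent_settings))
            elif scenario == "oxygenation_missing":
                b.add(30, ProtocolOrder(protocol="ventilation"))
                b.add(35, VentSettings(**adherent_settings))
            elif scenario == "cpap_breach":
                b.add(30, ProtocolOrder(protocol="ventilation"))
                b.add(35, VentSettings(mode=VentMode.cpap_ps, peep=12.0, fio2=0.40,
                                       pressure_support=10.0))
                charted_fio2["value"] = 0.40
            else:  # both_protocols_missing
                b.add(35, VentSettings(**adherent_settings))
        label = pos_label()
        report_labels.append(label)
        b.add(55, render_report(label, rng, spec.report_templates))
        b.add(60, BloodGas(pao2=qualifying_pao2()))

        clinician = f"MD{index % 97:03d}"
        t_open = 70 + rng.uniform(0, 15)
        b.add(t_open, ChartOpen(clinician_id=clinician, role=ClinicianRole.physician))

        planted_follow = bool(
            rng.random() < (spec.p_follow_specific if specific else spec.p_follow_adopt)
        )
        if planted_follow:
            t_fix = t_open + rng.uniform(5, 115)
        elif rng.random() < 0.5:
            t_fix = t_open + rng.uniform(125, 180)  # change lands, but too late
        else:
            t_fix = None
        if t_fix is not None:
            if specific:
                fixed = dict(adherent_settings)
                fixed.update(peep=14.0, fio2=0.80)  # on-grid at FiO2 0.80
                b.add(t_fix, VentSettings(**fixed))
                charted_fio2["value"] = 0.80
            else:
                if scenario in ("both_protocols_missing", "ventilation_missing"):
                    b.add(t_fix, ProtocolOrder(protocol="ventilation"))
                if scenario in ("both_protocols_missing", "oxygenation_missing", "cpap_breach"):
                    b.add(t_fix + 1, ProtocolOrder(protocol="oxygenation"))
                if scenario == "cpap_breach":
                    b.add(t_fix + 2, VentSettings(**adherent_settings))
                    charted_fio2["value"] = 0.60
        if rng.random() < spec.p_response:
            suppress = rng.random() < spec.p_suppressing_response / max(spec.p_response, 1e-9)
            action = ResponseAction.not_ards if suppress else ResponseAction.act_on_instruction
            b.add(t_open + 5, ClinicianResponse(clinician_id=clinician, action=action))
        b.add(t_open + 200, ChartClose(clinician_id=clinician))

    # extra qualifying blood gases: additional trigger events later in the stay
    for k in range(int(rng.poisson(max(spec.mean_triggers_per_encounter - 1.0, 0.0)))):
        b.add(300 + 30 * k + rng.uniform(0, 10), BloodGas(pao2=qualifying_pao2()))

    truth = GroundTruth(
        encounter_id=enc_id,
        site_id=site,
        possible_ards=kind != "no_ards",
        nonadherent=kind == "nonadherent",
        scenario=scenario,
        report_labels=report_labels,
        planted_follow=planted_follow,
        rec_category=rec_category,
    )
    return b.events, truth


def generate_cohort(
    spec: CohortSpec,
) -> tuple[dict[str, list[ChartEvent]], list[GroundTruth]]:
    """Generate a cohort event stream plus its ground-truth sidecar.

    Deterministic given ``spec.seed``; every encounter is schema-valid and
    carries at least one qualifying trigger.  The sidecar is for evaluation
    only and must never feed the engine.
    """
    rng = np.random.default_rng(spec.seed)
    encounters: dict[str, list[ChartEvent]] = {}
    truths: list[GroundTruth] = []
    for i in range(spec.n_encounters):
        events, truth = _generate_encounter(spec, rng, i)
        encounters[truth.encounter_id] = events
        truths.append(truth)
    return encounters, truths
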