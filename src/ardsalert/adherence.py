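"""Lung-protective-ventilation treatment detection.

Given a fired trigger with a positive bilateral-infiltrate detection, this
module checks the patient's current treatment against the computerized
ventilation and oxygenation protocols and emits typed recommendations.
Nine recommendation types exist, partitioned into two categories that
mirror how the alert messages are reported:

* *adopt_protocol* (7 types) — the clinician has not adopted the
  computerized protocols or is in an unacceptable ventilator mode;
* *specific_setting* (2 types) — the protocols are in use but a specific
  setting (PEEP/FiO2 combination, tidal volume) is out of range.

Specific-setting checks run only when the corresponding protocol has been
ordered: a patient with no protocols gets the adoption recommendation, not
a setting critique — the setting instructions come from the protocols
themselves.  Tidal volume is judged per predicted body weight (Devine);
when sex or height is uncharted the tidal-volume check is skipped and
flagged, never guessed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .config import EngineConfig, PeepFio2Grid
from .events import Sex, VentMode, VentSettings
from .infiltrates import DetectionResult
from .triggers import EncounterState, TriggerEvent

PBW_FLOOR_KG = 20.0


class RecommendationType(str, Enum):
    protocols_not_ordered = "protocols_not_ordered"
    cpap_ps_inappropriate = "cpap_ps_inappropriate"
    change_to_volume_control = "change_to_volume_control"
    nonstandard_mode = "nonstandard_mode"
    ventilation_protocol_not_ordered = "ventilation_protocol_not_ordered"
    noncompliant_mode = "noncompliant_mode"
    oxygenation_protocol_not_ordered = "oxygenation_protocol_not_ordered"
    peep_fio2_inappropriate = "peep_fio2_inappropriate"
    tidal_volume_too_large = "tidal_volume_too_large"


SPECIFIC_SETTING_TYPES = frozenset(
    {RecommendationType.peep_fio2_inappropriate, RecommendationType.tidal_volume_too_large}
)


class RecommendationCategory(str, Enum):
    adopt_protocol = "adopt_protocol"
    specific_setting = "specific_setting"


def category_of(rec_type: RecommendationType) -> RecommendationCategory:
    return (
        RecommendationCategory.specific_setting
        if rec_type in SPECIFIC_SETTING_TYPES
        else RecommendationCategory.adopt_protocol
    )


@dataclass(frozen=True)
class Recommendation:
    """One typed nonadherence finding with its evidence snapshot."""

    rec_type: RecommendationType
    created_at: dt.datetime
    evidence: dict = field(default_factory=dict)

    @property
    def category(self) -> RecommendationCategory:
        return category_of(self.rec_type)


@dataclass(frozen=True)
class PossibleARDSEvent:
    """A fired trigger plus positive infiltrate detection and the LPV verdict."""

    trigger: TriggerEvent
    infiltrates: DetectionResult
    lpv_adherent: bool
    recommendations: tuple[Recommendation, ...]

    def __post_init__(self):
        assert self.lpv_adherent == (len(self.recommendations) == 0)


def predicted_body_weight(sex: Sex, height_cm: float) -> float:
    """Devine predicted body weight in kg, floored at 20 kg.

    male: 50 + 0.91*(height-152.4); female: 45.5 + 0.91*(height-152.4).
    """
    if not (120.0 <= height_cm <= 230.0):
        raise ValueError(f"height {height_cm} cm outside plausible range [120, 230]")
    base = 50.0 if sex is Sex.male else 45.5
    return max(base + 0.91 * (height_cm - 152.4), PBW_FLOOR_KG)


def check_tidal_volume(
    settings: VentSettings, pbw: float, cfg: EngineConfig, now: dt.datetime
) -> Optional[Recommendation]:
    """Flag tidal volume strictly above ``vt_per_pbw_max`` mL/kg PBW."""
    if settings.tidal_volume is None:
        return None
    vt_per_kg = settings.tidal_volume / pbw
    if vt_per_kg > cfg.vt_per_pbw_max + 1e-9:
        return Recommendation(
            RecommendationType.tidal_volume_too_large,
            created_at=now,
            evidence={
                "tidal_volume": settings.tidal_volume,
                "pbw": round(pbw, 2),
                "vt_per_kg": round(vt_per_kg, 3),
                "limit": cfg.vt_per_pbw_max,
            },
        )
    return None


def check_peep_fio2(
    settings: VentSettings, grid: PeepFio2Grid, now: dt.datetime
) -> Optional[Recommendation]:
    """Flag a PEEP outside tolerance of the grid's allowed set at the charted FiO2."""
    if settings.peep is None or settings.fio2 is None:
        return None
    if grid.is_adherent(settings.fio2, settings.peep):
        return None
    level = grid.level_for(settings.fio2)
    return Recommendation(
        RecommendationType.peep_fio2_inappropriate,
        created_at=now,
        evidence={
            "fio2": settings.fio2,
            "peep": settings.peep,
            "grid": grid.name,
            "grid_level": level,
            "allowed_peep": grid.allowed_pairs[level],
        },
    )


def check_mode_rules(
    settings: VentSettings, cfg: EngineConfig, now: dt.datetime
) -> list[Recommendation]:
    """Mode-policy recommendations; at most one fires per settings snapshot.

    CPAP/PS is inappropriate when PEEP > 10, FiO2 > 0.50 or PS > 15;
    unrecognized modes draw `nonstandard_mode`; recognized but
    system-noncompliant modes draw `noncompliant_mode`; a compliant
    non-volume-control mode draws the volume-control suggestion.
    """
    mode = settings.mode
    evidence = {
        "mode": mode.value,
        "peep": settings.peep,
        "fio2": settings.fio2,
        "pressure_support": settings.pressure_support,
    }
    if mode is VentMode.cpap_ps:
        lim = cfg.cpap_ps_limits
        branches = []
        if settings.peep is not None and settings.peep > lim.peep:
            branches.append("peep")
        if settings.fio2 is not None and settings.fio2 > lim.fio2 + 1e-9:
            branches.append("fio2")
        if settings.pressure_support is not None and settings.pressure_support > lim.pressure_support:
            branches.append("pressure_support")
        if branches:
            return [
                Recommendation(
                    RecommendationType.cpap_ps_inappropriate,
                    created_at=now,
                    evidence={**evidence, "breached": branches},
                )
            ]
        return []
    if mode not in cfg.standard_modes:
        return [Recommendation(RecommendationType.nonstandard_mode, now, evidence)]
    if mode not in cfg.compliant_modes:
        return [Recommendation(RecommendationType.noncompliant_mode, now, evidence)]
    if mode is not VentMode.volume_control:
        return [Recommendation(RecommendationType.change_to_volume_control, now, evidence)]
    return []


def check_protocol_orders(
    ventilation_ordered: bool, oxygenation_ordered: bool, now: dt.datetime
) -> list[Recommendation]:
    """Protocol-adoption recommendations; outputs are mutually exclusive."""
    if not ventilation_ordered and not oxygenation_ordered:
        return [Recommendation(RecommendationType.protocols_not_ordered, now, {})]
    if not ventilation_ordered:
        return [Recommendation(RecommendationType.ventilation_protocol_not_ordered, now, {})]
    if not oxygenation_ordered:
        return [Recommendation(RecommendationType.oxygenation_protocol_not_ordered, now, {})]
    return []


def assess_lpv(
    trigger: TriggerEvent,
    detection: DetectionResult,
    state: EncounterState,
    cfg: EngineConfig,
) -> Optional[PossibleARDSEvent]:
    """Build the possible-ARDS event and its recommendation set.

    Requires a positive infiltrate detection and re-checks the qualifying
    P/F ratio at treatment-detection time.  Returns ``None`` (indeterminate,
    no alert) when no ventilator settings were ever charted.  The result is
    a pure function of (trigger, latest state, config).
    """
    if not detection.positive:
        return None
    phys = trigger.physiology
    if phys is None or phys.pf_ratio_adjusted > cfg.pf_threshold:
        return None
    settings: Optional[VentSettings] = state.last_settings
    if settings is None:
        return None

    now = trigger.timestamp
    recs: list[Recommendation] = []
    recs += check_protocol_orders(state.ventilation_ordered, state.oxygenation_ordered, now)
    recs += check_mode_rules(settings, cfg, now)
    if state.ventilation_ordered:
        attrs = state.attrs
        if attrs is not None and attrs.sex is not None and attrs.height_cm is not None:
            pbw = predicted_body_weight(attrs.sex, attrs.height_cm)
            rec = check_tidal_volume(settings, pbw, cfg, now)
            if rec:
                recs.append(rec)
        # else: PBW undefined -> tidal-volume check skipped, not guessed
    if state.oxygenation_ordered:
        rec = check_peep_fio2(settings, cfg.active_grid, now)
        if rec:
            recs.append(rec)

    return PossibleARDSEvent(
        trigger=trigger,
        infiltrates=detection,
        lpv_adherent=not recs,
        recommendations=tuple(recs),
    )


def resolves(rec: Recommendation, payload, cfg: EngineConfig, *, orders_state: dict) -> bool:
    """Whether one subsequent event payload resolves a recommendation.

    Used both for the "addressed before chart close" reminder rule and for
    the followed-within-2-h service metric.  ``orders_state`` accumulates
    protocol orders across calls so the combined adopt-both-protocols
    recommendation resolves only once both orders are seen.
    """
    t = rec.rec_type
    if payload.type == "protocol_order":
        orders_state[payload.protocol] = True
        if t is RecommendationType.protocols_not_ordered:
            return orders_state.get("ventilation") and orders_state.get("oxygenation")
        if t is RecommendationType.ventilation_protocol_not_ordered:
            return payload.protocol == "ventilation"
        if t is RecommendationType.oxygenation_protocol_not_ordered:
            return payload.protocol == "oxygenation"
        return False
    if payload.type != "vent_settings":
        return False
    s: VentSettings = payload
    if t is RecommendationType.cpap_ps_inappropriate:
        return not check_mode_rules(s, cfg, rec.created_at) or s.mode is not VentMode.cpap_ps
    if t is RecommendationType.change_to_volume_control:
        return s.mode is VentMode.volume_control
    if t is RecommendationType.nonstandard_mode:
        return s.mode in cfg.standard_modes
    if t is RecommendationType.noncompliant_mode:
        return s.mode in cfg.compliant_modes
    if t is RecommendationType.peep_fio2_inappropriate:
        return (
            s.peep is not None
            and s.fio2 is not None
            and cfg.active_grid.is_adherent(s.fio2, s.peep)
        )
    if t is RecommendationType.tidal_volume_too_large:
        pbw = rec.evidence.get("pbw")
        return (
            pbw is not None
            and s.tidal_volume is not None
            and s.tidal_volume / pbw <= cfg.vt_per_pbw_max + 1e-9
        )
    return False
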