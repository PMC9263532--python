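"""Trigger physiology, inclusion/exclusion screening, and the incremental
engine's agreement with a from-scratch re-evaluation oracle."""

import datetime as dt

import numpy as np
import pytest

from ardsalert.config import EngineConfig
from ardsalert.events import AirwayStatus, BloodGas, RadiographReport, VentMode, VentSettings
from ardsalert.triggers import (
    EncounterState,
    TriggerCause,
    TriggerDecision,
    compute_pf_ratio,
    evaluate_exclusion,
    evaluate_inclusion,
    process_event,
)

from .conftest import T0, StreamBuilder, make_attrs, random_stream


class TestPfRatio:
    def test_identity_factor(self):
        phys = compute_pf_ratio(100, 1.0, 760)
        assert phys.pf_ratio == pytest.approx(100)
        assert phys.pf_ratio_adjusted == pytest.approx(100)

    def test_plain_arithmetic(self):
        assert compute_pf_ratio(82, 0.40, 760).pf_ratio == pytest.approx(205)

    def test_altitude_adjustment(self):
        # 205 * 760/646 = 241.18...
        phys = compute_pf_ratio(82, 0.40, 646)
        assert phys.pf_ratio_adjusted == pytest.approx(205 * 760 / 646)
        assert phys.pf_ratio_adjusted == pytest.approx(241.2, abs=0.05)

    @pytest.mark.parametrize("pao2, fio2", [(0, 0.5), (-5, 0.5), (80, 0.1), (80, 1.5)])
    def test_domain_errors(self, pao2, fio2):
        with pytest.raises(ValueError):
            compute_pf_ratio(pao2, fio2)


class TestInclusion:
    def test_minor_fails_age(self, cfg):
        attrs = make_attrs(age=17)
        phys = compute_pf_ratio(80, 0.6)
        failed = evaluate_inclusion(attrs, phys, T0, T0 + dt.timedelta(hours=1), cfg)
        assert failed == ["age<18"]

    def test_threshold_is_inclusive(self, cfg):
        phys = compute_pf_ratio(255 * 0.6, 0.6)
        assert phys.pf_ratio_adjusted == pytest.approx(255)
        failed = evaluate_inclusion(make_attrs(), phys, T0, T0 + dt.timedelta(hours=1), cfg)
        assert "pf_ratio_above_threshold" not in failed

    def test_intubation_window(self, cfg):
        attrs = make_attrs(intubation_time=T0 - dt.timedelta(days=5))
        failed = evaluate_inclusion(attrs, compute_pf_ratio(80, 0.6), T0, T0, cfg)
        assert "intubated_over_window" in failed

    def test_stale_vent_mode(self, cfg):
        failed = evaluate_inclusion(
            make_attrs(), compute_pf_ratio(80, 0.6),
            T0 - dt.timedelta(days=8), T0, cfg,
        )
        assert "vent_mode_stale" in failed

    def test_unknown_intubation_time_flagged(self, cfg):
        attrs = make_attrs(intubation_time=None, airway_status=AirwayStatus.intubated)
        failed = evaluate_inclusion(attrs, compute_pf_ratio(80, 0.6), T0, T0, cfg)
        assert "intubation_time_unknown" in failed

    def test_all_failures_reported_not_just_first(self, cfg):
        attrs = make_attrs(age=10, intubation_time=T0 - dt.timedelta(days=6))
        failed = evaluate_inclusion(attrs, None, None, T0, cfg)
        assert set(failed) >= {"age<18", "vent_mode_never_charted", "pf_ratio_unavailable"}


class TestExclusion:
    @pytest.mark.parametrize(
        "overrides, reason",
        [
            ({"pa_catheter": True}, "pulmonary_artery_catheter"),
            ({"airway_status": AirwayStatus.t_piece}, "t_piece_or_trach_mask"),
            ({"airway_status": AirwayStatus.trach_mask}, "t_piece_or_trach_mask"),
            ({"palliative_care": True}, "palliative_care"),
            ({"on_mcs": True}, "mechanical_circulatory_support"),
            ({"attending_specialty": "Cardiothoracic Surgery"}, "cardiothoracic_attending"),
        ],
    )
    def test_each_criterion(self, overrides, reason):
        assert reason in evaluate_exclusion(make_attrs(**overrides))

    def test_clean_patient_not_excluded(self):
        assert evaluate_exclusion(make_attrs()) == []


class TestProcessEvent:
    def _qualified_state(self, cfg):
        state = EncounterState()
        b = StreamBuilder()
        b.at(0, make_attrs())
        b.at(5, VentSettings(mode=VentMode.volume_control, fio2=0.6, peep=10))
        for e in b.build():
            state.observe(e)
        return state

    def test_radiograph_triggers_with_recent_physiology(self, cfg):
        state = self._qualified_state(cfg)
        gas = StreamBuilder().at(10, BloodGas(pao2=90)).build()[0]
        state.observe(gas)
        assert process_event(gas, state, cfg).decision is TriggerDecision.fired
        xray = StreamBuilder().at(20, RadiographReport(report_text="...")).build()[0]
        trig = process_event(xray, state, cfg)
        assert trig.cause is TriggerCause.new_chest_xray
        assert trig.fired

    def test_vent_settings_never_trigger(self, cfg):
        state = self._qualified_state(cfg)
        ev = StreamBuilder().at(10, VentSettings(mode=VentMode.volume_control, fio2=0.5)).build()[0]
        state.observe(ev)
        assert process_event(ev, state, cfg) is None

    def test_high_pf_excluded_with_reason(self, cfg):
        state = self._qualified_state(cfg)
        gas = StreamBuilder().at(10, BloodGas(pao2=300)).build()[0]  # P/F 500
        state.observe(gas)
        trig = process_event(gas, state, cfg)
        assert trig.decision is TriggerDecision.excluded
        assert "pf_ratio_above_threshold" in trig.exclusion_reasons

    def test_no_fio2_ever_charted_no_trigger(self, cfg):
        state = EncounterState()
        ev = StreamBuilder().at(0, make_attrs()).build()[0]
        state.observe(ev)
        gas = StreamBuilder().at(10, BloodGas(pao2=60)).build()[0]
        state.observe(gas)
        assert process_event(gas, state, cfg) is None

    def test_monotone_in_pao2(self, cfg):
        """Lowering PaO2 (all else fixed) never flips fired -> excluded-by-P/F."""
        for pao2 in np.linspace(250, 10, 25):
            state = self._qualified_state(cfg)
            gas = StreamBuilder().at(10, BloodGas(pao2=float(pao2))).build()[0]
            state.observe(gas)
            trig = process_event(gas, state, cfg)
            if pao2 / 0.6 <= cfg.pf_threshold:
                assert "pf_ratio_above_threshold" not in trig.exclusion_reasons


def brute_force_decisions(events, cfg: EngineConfig):
    """Oracle: re-derive the screening state from the full prefix at each event.

    Independent of EncounterState — scans the prefix for the latest
    attributes, FiO2, blood gas and mode time, then applies the screening
    table directly.
    """
    decisions = []
    for i, ev in enumerate(events):
        kind = ev.payload.type
        if kind not in ("blood_gas", "radiograph_report"):
            continue
        prefix = events[: i + 1]
        attrs = next((e.payload for e in reversed(prefix) if e.payload.type == "patient_attrs"), None)

        def fio2_at(t):
            for e in reversed(prefix):
                if e.payload.type == "vent_settings" and e.payload.fio2 is not None and e.timestamp <= t:
                    return e.payload.fio2, e.timestamp
            return None, None

        if kind == "blood_gas":
            fio2, _ = fio2_at(ev.timestamp)
            pair = (ev.payload.pao2, fio2) if fio2 else None
        else:
            pair = None
            for e in reversed(prefix):
                if e.payload.type == "blood_gas":
                    fio2, _ = fio2_at(e.timestamp)
                    if fio2:
                        pair = (e.payload.pao2, fio2)
                    break
        if pair is None or attrs is None:
            decisions.append((ev.event_id, None, None))
            continue

        adj = (pair[0] / pair[1]) * (760 / cfg.barometric_pressure)
        mode_time = next(
            (e.timestamp for e in reversed(prefix) if e.payload.type == "vent_settings"), None
        )
        reasons = []
        if attrs.age < cfg.min_age:
            reasons.append("age")
        if mode_time is None or (ev.timestamp - mode_time) >= dt.timedelta(days=7):
            reasons.append("mode")
        if adj > cfg.pf_threshold:
            reasons.append("pf")
        if attrs.intubation_time is None or (
            ev.timestamp - attrs.intubation_time
        ) > dt.timedelta(days=4):
            reasons.append("intubation")
        if evaluate_exclusion(attrs):
            reasons.append("excluded")
        decisions.append((ev.event_id, not reasons, adj))
    return decisions


def test_incremental_engine_matches_bruteforce_oracle(cfg):
    """On random streams <= 50 events the incremental screening decisions
    equal a from-scratch re-evaluation of the full state at each event."""
    rng = np.random.default_rng(20260901)
    for _ in range(200):
        events = random_stream(rng, max_events=50)
        state = EncounterState()
        incremental = []
        for ev in events:
            state.observe(ev)
            trig = process_event(ev, state, cfg)
            if ev.payload.type in ("blood_gas", "radiograph_report"):
                incremental.append(
                    (ev.event_id,
                     None if trig is None else trig.fired,
                     None if trig is None else trig.physiology.pf_ratio_adjusted)
                )
        oracle = brute_force_decisions(events, cfg)
        assert len(incremental) == len(oracle)
        for (eid_a, fired_a, adj_a), (eid_b, fired_b, adj_b) in zip(incremental, oracle):
            assert eid_a == eid_b
            assert fired_a == fired_b
            if adj_a is not None and adj_b is not None:
                assert adj_a == pytest.approx(adj_b)


def test_determinism_identical_prefixes(cfg):
    rng = np.random.default_rng(5)
    events = random_stream(rng, max_events=30)

    def run():
        state = EncounterState()
        out = []
        for ev in events:
            state.observe(ev)
            trig = process_event(ev, state, cfg)
            if trig:
                out.append((trig.event_id, trig.decision, trig.exclusion_reasons))
        return out

    assert run() == run()
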