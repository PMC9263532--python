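"""LPV treatment detection: PBW, tidal volume, PEEP/FiO2 grid, mode and
protocol-order rules, and the aggregated possible-ARDS assessment."""

import datetime as dt

import pytest

from ardsalert.adherence import (
    RecommendationCategory,
    RecommendationType,
    SPECIFIC_SETTING_TYPES,
    assess_lpv,
    category_of,
    check_mode_rules,
    check_peep_fio2,
    check_protocol_orders,
    check_tidal_volume,
    predicted_body_weight,
    resolves,
)
from ardsalert.config import EngineConfig
from ardsalert.events import (
    BloodGas,
    ProtocolOrder,
    RadiographReport,
    Sex,
    VentMode,
    VentSettings,
)
from ardsalert.infiltrates import DetectionResult
from ardsalert.triggers import EncounterState, process_event

from .conftest import T0, POSITIVE_REPORT, StreamBuilder, make_attrs

NOW = T0


class TestPredictedBodyWeight:
    def test_formula_anchor_points(self):
        assert predicted_body_weight(Sex.male, 152.4) == pytest.approx(50.0)
        assert predicted_body_weight(Sex.female, 152.4) == pytest.approx(45.5)

    def test_male_175cm(self):
        assert predicted_body_weight(Sex.male, 175.0) == pytest.approx(70.566, abs=0.01)

    def test_floor(self):
        assert predicted_body_weight(Sex.female, 122.0) == pytest.approx(20.0)

    @pytest.mark.parametrize("height", [100, 119.9, 231])
    def test_implausible_height_rejected(self, height):
        with pytest.raises(ValueError):
            predicted_body_weight(Sex.male, height)


class TestTidalVolume:
    def _settings(self, vt):
        return VentSettings(mode=VentMode.volume_control, tidal_volume=vt)

    def test_below_limit_adherent(self, cfg):
        assert check_tidal_volume(self._settings(420), 70.0, cfg, NOW) is None

    def test_above_limit_flagged(self, cfg):
        rec = check_tidal_volume(self._settings(500), 70.566, cfg, NOW)
        assert rec.rec_type is RecommendationType.tidal_volume_too_large
        assert rec.evidence["vt_per_kg"] == pytest.approx(7.086, abs=0.01)

    def test_boundary_exactly_at_limit_adherent(self, cfg):
        pbw = 70.566
        assert check_tidal_volume(self._settings(6.5 * pbw), pbw, cfg, NOW) is None


class TestPeepFio2:
    def test_on_grid_adherent(self, cfg):
        s = VentSettings(mode=VentMode.volume_control, fio2=0.40, peep=5)
        assert check_peep_fio2(s, cfg.active_grid, NOW) is None

    def test_far_off_grid_flagged(self, cfg):
        s = VentSettings(mode=VentMode.volume_control, fio2=1.0, peep=5)
        rec = check_peep_fio2(s, cfg.active_grid, NOW)
        assert rec.rec_type is RecommendationType.peep_fio2_inappropriate
        assert rec.evidence["grid_level"] == pytest.approx(1.0)

    def test_within_tolerance_adherent(self, cfg):
        # allowed 8 at FiO2 0.40, charted 9, tolerance 1
        s = VentSettings(mode=VentMode.volume_control, fio2=0.40, peep=9)
        assert check_peep_fio2(s, cfg.active_grid, NOW) is None

    def test_nearest_not_above_level(self, cfg):
        assert cfg.active_grid.level_for(0.45) == pytest.approx(0.40)
        assert cfg.active_grid.level_for(0.25) == pytest.approx(0.30)


class TestModeRules:
    def test_cpap_peep_branch(self, cfg):
        s = VentSettings(mode=VentMode.cpap_ps, peep=12, fio2=0.40, pressure_support=10)
        (rec,) = check_mode_rules(s, cfg, NOW)
        assert rec.rec_type is RecommendationType.cpap_ps_inappropriate
        assert rec.evidence["breached"] == ["peep"]

    def test_cpap_all_below_limits(self, cfg):
        s = VentSettings(mode=VentMode.cpap_ps, peep=8, fio2=0.45, pressure_support=12)
        assert check_mode_rules(s, cfg, NOW) == []

    def test_cpap_fio2_branch(self, cfg):
        s = VentSettings(mode=VentMode.cpap_ps, peep=5, fio2=0.51, pressure_support=5)
        (rec,) = check_mode_rules(s, cfg, NOW)
        assert "fio2" in rec.evidence["breached"]

    def test_nonstandard_mode(self, cfg):
        s = VentSettings(mode=VentMode.aprv)
        (rec,) = check_mode_rules(s, cfg, NOW)
        assert rec.rec_type is RecommendationType.nonstandard_mode

    def test_noncompliant_mode(self, cfg):
        s = VentSettings(mode=VentMode.simv)
        (rec,) = check_mode_rules(s, cfg, NOW)
        assert rec.rec_type is RecommendationType.noncompliant_mode

    def test_volume_control_suggestion(self, cfg):
        s = VentSettings(mode=VentMode.pressure_control)
        (rec,) = check_mode_rules(s, cfg, NOW)
        assert rec.rec_type is RecommendationType.change_to_volume_control

    def test_volume_control_clean(self, cfg):
        assert check_mode_rules(VentSettings(mode=VentMode.volume_control), cfg, NOW) == []


class TestProtocolOrders:
    def test_both_missing_combined_type(self):
        (rec,) = check_protocol_orders(False, False, NOW)
        assert rec.rec_type is RecommendationType.protocols_not_ordered

    def test_only_oxygenation_missing(self):
        (rec,) = check_protocol_orders(True, False, NOW)
        assert rec.rec_type is RecommendationType.oxygenation_protocol_not_ordered

    def test_only_ventilation_missing(self):
        (rec,) = check_protocol_orders(False, True, NOW)
        assert rec.rec_type is RecommendationType.ventilation_protocol_not_ordered

    def test_both_ordered(self):
        assert check_protocol_orders(True, True, NOW) == []


class TestTaxonomy:
    def test_nine_types_partitioned_seven_two(self):
        all_types = list(RecommendationType)
        assert len(all_types) == 9
        assert len(SPECIFIC_SETTING_TYPES) == 2
        adopt = [t for t in all_types if category_of(t) is RecommendationCategory.adopt_protocol]
        assert len(adopt) == 7


def _qualified_state(*, orders=True, settings=None):
    state = EncounterState()
    b = StreamBuilder()
    b.at(0, make_attrs())
    if orders:
        b.at(5, ProtocolOrder(protocol="ventilation"))
        b.at(6, ProtocolOrder(protocol="oxygenation"))
    b.at(10, settings or VentSettings(
        mode=VentMode.volume_control, fio2=0.6, peep=10, tidal_volume=420,
        pressure_support=0))
    for e in b.build():
        state.observe(e)
    return state


def _fired_trigger(state, cfg, pao2=90):
    gas = StreamBuilder().at(20, BloodGas(pao2=pao2)).build()[0]
    state.observe(gas)
    trig = process_event(gas, state, cfg)
    assert trig.fired
    return trig


POSITIVE = DetectionResult(positive=True)


class TestAssessLpv:
    def test_fully_adherent_no_alert(self, cfg):
        state = _qualified_state()
        event = assess_lpv(_fired_trigger(state, cfg), POSITIVE, state, cfg)
        assert event.lpv_adherent and event.recommendations == ()

    def test_multiple_recommendations_in_one_event(self, cfg):
        # oxygenation protocol missing AND an inappropriate CPAP/PS snapshot
        state = EncounterState()
        b = StreamBuilder()
        b.at(0, make_attrs())
        b.at(5, ProtocolOrder(protocol="ventilation"))
        b.at(10, VentSettings(mode=VentMode.cpap_ps, peep=12, fio2=0.40, pressure_support=10))
        for e in b.build():
            state.observe(e)
        event = assess_lpv(_fired_trigger(state, cfg, pao2=60), POSITIVE, state, cfg)
        types = {r.rec_type for r in event.recommendations}
        assert types == {
            RecommendationType.oxygenation_protocol_not_ordered,
            RecommendationType.cpap_ps_inappropriate,
        }
        assert not event.lpv_adherent

    def test_settings_checks_gated_on_protocol_adoption(self, cfg):
        """Without any protocol ordered the finding is the adoption gap, not
        a setting critique - setting instructions come from the protocols."""
        state = _qualified_state(
            orders=False,
            settings=VentSettings(mode=VentMode.volume_control, fio2=1.0, peep=5,
                                  tidal_volume=900),
        )
        event = assess_lpv(_fired_trigger(state, cfg), POSITIVE, state, cfg)
        assert [r.rec_type for r in event.recommendations] == [
            RecommendationType.protocols_not_ordered
        ]

    def test_negative_detection_yields_nothing(self, cfg):
        state = _qualified_state()
        trig = _fired_trigger(state, cfg)
        assert assess_lpv(trig, DetectionResult(positive=False), state, cfg) is None

    def test_indeterminate_without_settings(self, cfg):
        state = EncounterState()
        for e in StreamBuilder().at(0, make_attrs()).build():
            state.observe(e)
        # physiology cannot exist without FiO2, so build a synthetic trigger
        from ardsalert.triggers import TriggerDecision, TriggerEvent, compute_pf_ratio

        trig = TriggerEvent(
            encounter_id="E1", event_id=9, timestamp=NOW,
            cause="new_pao2", physiology=compute_pf_ratio(80, 0.6),
            decision=TriggerDecision.fired,
        )
        assert assess_lpv(trig, POSITIVE, state, cfg) is None

    def test_pure_function_of_state(self, cfg):
        state = _qualified_state()
        trig = _fired_trigger(state, cfg)
        a = assess_lpv(trig, POSITIVE, state, cfg)
        b = assess_lpv(trig, POSITIVE, state, cfg)
        assert a.recommendations == b.recommendations

    def test_missing_height_skips_tidal_volume_check(self, cfg):
        state = EncounterState()
        b = StreamBuilder()
        b.at(0, make_attrs(height_cm=None))
        b.at(5, ProtocolOrder(protocol="ventilation"))
        b.at(6, ProtocolOrder(protocol="oxygenation"))
        b.at(10, VentSettings(mode=VentMode.volume_control, fio2=0.6, peep=10,
                              tidal_volume=900))
        for e in b.build():
            state.observe(e)
        event = assess_lpv(_fired_trigger(state, cfg), POSITIVE, state, cfg)
        types = {r.rec_type for r in event.recommendations}
        assert RecommendationType.tidal_volume_too_large not in types

    def test_tightening_vt_threshold_never_removes_recommendations(self):
        """Monotonicity: a stricter tidal-volume limit only adds findings."""
        loose = EngineConfig(vt_per_pbw_max=8.0)
        tight = EngineConfig(vt_per_pbw_max=6.0)
        for vt in (350, 420, 460, 500, 560, 650):
            settings = VentSettings(mode=VentMode.volume_control, fio2=0.6,
                                    peep=10, tidal_volume=vt)
            loose_rec = check_tidal_volume(settings, 70.0, loose, NOW)
            tight_rec = check_tidal_volume(settings, 70.0, tight, NOW)
            if loose_rec is not None:
                assert tight_rec is not None


class TestResolves:
    def _rec(self, rec_type, **evidence):
        from ardsalert.adherence import Recommendation

        return Recommendation(rec_type, NOW, evidence)

    def test_combined_order_rec_needs_both_orders(self, cfg):
        rec = self._rec(RecommendationType.protocols_not_ordered)
        orders_state = {}
        assert not resolves(rec, ProtocolOrder(protocol="ventilation"), cfg, orders_state=orders_state)
        assert resolves(rec, ProtocolOrder(protocol="oxygenation"), cfg, orders_state=orders_state)

    def test_setting_rec_resolved_by_compliant_settings(self, cfg):
        rec = self._rec(RecommendationType.peep_fio2_inappropriate)
        good = VentSettings(mode=VentMode.volume_control, fio2=0.40, peep=5)
        bad = VentSettings(mode=VentMode.volume_control, fio2=1.0, peep=5)
        assert resolves(rec, good, cfg, orders_state={})
        assert not resolves(rec, bad, cfg, orders_state={})

    def test_vt_rec_uses_evidence_pbw(self, cfg):
        rec = self._rec(RecommendationType.tidal_volume_too_large, pbw=70.0)
        good = VentSettings(mode=VentMode.volume_control, tidal_volume=420)
        assert resolves(rec, good, cfg, orders_state={})
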