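"""Service-outcome and accuracy statistics for the alert engine.

Implements the implementation-research estimands the tool is evaluated on:

* **initial guideline nonadherence** — encounters with >=1 possible-ARDS
  event lacking detected LPV treatment, over encounters with >=1 fired
  trigger event;
* **recommendation adherence** — recommendations followed (a consistent
  treatment change within a configurable window, default 2 h, after alert
  delivery) over recommendations sent, overall and by category/type;
* **alerts prevented** — per site, (possible-ARDS events − nonadherent
  events) x mean alerts per nonadherent event: the messages a pure
  disease-detection alert would have sent for already-adherent care;
* binomial confidence intervals (Wald and Clopper–Pearson exact), a
  two-proportion z comparison, screening contingency metrics, and a
  nonparametric AUROC with the Hanley–McNeil standard error.
"""

from __future__ import annotations

import datetime as dt
import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .adherence import Recommendation, RecommendationType, category_of, resolves
from .config import EngineConfig
from .engine import EncounterLedger


def round_half_up(x: float, digits: int = 0) -> float:
    """Decimal half-up rounding, matching how report tables are printed."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# encounter summaries

@dataclass
class EncounterSummary:
    """Per-encounter aggregates feeding every service metric."""

    encounter_id: str
    site_id: Optional[str] = None
    n_trigger_events: int = 0
    n_possible_ards_events: int = 0
    n_nonadherent_events: int = 0
    n_alerts_sent: int = 0
    rec_sent: Counter = field(default_factory=Counter)
    rec_followed: Counter = field(default_factory=Counter)

    def __post_init__(self):
        for n in (self.n_trigger_events, self.n_possible_ards_events,
                  self.n_nonadherent_events, self.n_alerts_sent):
            if n < 0:
                raise ValueError("counts must be nonnegative")


def classify_followed(
    rec: Recommendation,
    delivered_at: dt.datetime,
    subsequent_events: Iterable[tuple[dt.datetime, object]],
    cfg: EngineConfig,
    window_minutes: Optional[float] = None,
) -> bool:
    """Was a consistent treatment change charted within the window after delivery?

    Order-type recommendations need the missing protocol order(s); setting-
    type recommendations need settings moved into compliance.  Events are
    ``(timestamp, payload)`` pairs; only those inside the window count.
    """
    window = dt.timedelta(minutes=window_minutes or cfg.adherence_window_minutes)
    orders_state: dict = {}
    for ts, payload in subsequent_events:
        if ts <= delivered_at or ts > delivered_at + window:
            continue
        if resolves(rec, payload, cfg, orders_state=orders_state):
            return True
    return False


def summarize_encounter(ledger: EncounterLedger, cfg: EngineConfig) -> EncounterSummary:
    """Condense one encounter ledger into the metric aggregates."""
    summary = EncounterSummary(
        encounter_id=ledger.encounter_id,
        site_id=ledger.site_id,
        n_trigger_events=len(ledger.fired_triggers),
        n_possible_ards_events=len(ledger.possible_events),
        n_nonadherent_events=len(ledger.nonadherent_events),
        n_alerts_sent=len(ledger.alerts),
    )
    timeline = [(e.timestamp, e.payload) for e in ledger.events]
    for alert in ledger.alerts:
        for rec in alert.recommendations:
            summary.rec_sent[rec.rec_type] += 1
            if classify_followed(rec, alert.delivered_at, timeline, cfg):
                summary.rec_followed[rec.rec_type] += 1
    return summary


# ---------------------------------------------------------------------------
# service outcomes

def initial_nonadherence(summaries: Sequence[EncounterSummary]) -> float:
    """Encounters with >=1 nonadherent possible-ARDS event / encounters with >=1 trigger."""
    eligible = [s for s in summaries if s.n_trigger_events > 0]
    if not eligible:
        raise ValueError("no encounters with a trigger event; measure undefined")
    hit = sum(1 for s in eligible if s.n_nonadherent_events > 0)
    return hit / len(eligible)


def recommendation_adherence(followed_count: int, total_count: int) -> float:
    """Proportion of sent recommendations followed within the window."""
    if total_count <= 0:
        raise ValueError("recommendation adherence undefined with zero recommendations")
    if not (0 <= followed_count <= total_count):
        raise ValueError("followed count outside [0, total]")
    return followed_count / total_count


def mean_alerts_per_event(n_alerts: int, n_nonadherent_events: int) -> float:
    if n_nonadherent_events <= 0:
        raise ValueError("mean alerts per event undefined with zero nonadherent events")
    return n_alerts / n_nonadherent_events


def alerts_prevented(
    per_site: Sequence[tuple[int, int, int]],
) -> tuple[float, float]:
    """Estimated alert messages avoided by gating alerts on LPV nonadherence.

    ``per_site`` rows are (n_possible_ards_events, n_nonadherent_events,
    n_alerts_sent).  A site with zero nonadherent events has no observed
    alerting rate and contributes zero.  Returns (count, percent of the
    alerts that would have been sent without the gate).
    """
    prevented = 0.0
    sent = 0
    for possible, nonadherent, alerts in per_site:
        if possible < nonadherent:
            raise ValueError("possible-ARDS events cannot be fewer than nonadherent events")
        sent += alerts
        if nonadherent > 0:
            prevented += (possible - nonadherent) * (alerts / nonadherent)
    total = prevented + sent
    percent = 100.0 * prevented / total if total > 0 else 0.0
    return prevented, percent


# ---------------------------------------------------------------------------
# interval estimates

def binomial_ci(k: int, n: int, method: str = "clopper_pearson", alpha: float = 0.05):
    """95% binomial CI: Wald (normal) or Clopper–Pearson exact, in [0, 1]."""
    if n <= 0:
        raise ValueError("binomial CI undefined for n = 0")
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    sm_method = {"wald": "normal", "clopper_pearson": "beta"}[method]
    lo, hi = proportion_confint(k, n, alpha=alpha, method=sm_method)
    return max(0.0, float(lo)), min(1.0, float(hi))


def proportion_difference_ci(k1: int, n1: int, k2: int, n2: int, alpha: float = 0.05):
    """Difference p2 - p1 with Wald 95% CI and two-sided z-test p-value.

    Degenerate SE (both proportions at a boundary) falls back to a
    continuity-corrected SE using (k+0.5)/(n+1) so the interval and test
    remain defined.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both groups need at least one trial")
    p1, p2 = k1 / n1, k2 / n2
    diff = p2 - p1
    se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    if se == 0.0:
        c1, c2 = (k1 + 0.5) / (n1 + 1), (k2 + 0.5) / (n2 + 1)
        se = math.sqrt(c1 * (1 - c1) / n1 + c2 * (1 - c2) / n2)
    z = norm.ppf(1 - alpha / 2)
    ci = (diff - z * se, diff + z * se)
    p_value = 2 * norm.sf(abs(diff) / se)
    return diff, ci, p_value


# ---------------------------------------------------------------------------
# screening accuracy

@dataclass(frozen=True)
class ContingencyTable:
    """Screen-positive vs gold-standard 2x2 counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


def contingency_metrics(t: ContingencyTable, ci_method: str = "wald") -> dict:
    """Sensitivity/specificity/FPR/PPV/NPV/accuracy, each with a 95% CI.

    A metric whose denominator is zero is undefined and reported as None.
    """
    def metric(k, n):
        if n == 0:
            return None
        return {"value": k / n, "ci95": binomial_ci(k, n, method=ci_method), "k": k, "n": n}

    return {
        "sensitivity": metric(t.tp, t.tp + t.fn),
        "specificity": metric(t.tn, t.fp + t.tn),
        "fpr": metric(t.fp, t.fp + t.tn),
        "ppv": metric(t.tp, t.tp + t.fp),
        "npv": metric(t.tn, t.tn + t.fn),
        "accuracy": metric(t.tp + t.tn, t.total),
    }


@dataclass(frozen=True)
class AurocResult:
    auc: float
    se: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    q1: float
    q2: float


def auroc_hanley_mcneil(t: ContingencyTable) -> AurocResult:
    """Nonparametric AUROC for a binary screen, Hanley–McNeil standard error.

    With a single threshold the empirical AUROC is the probability a random
    diseased case outranks a random non-diseased case, giving ties half
    credit: A = (tp*tn + 0.5*(tp*fp + fn*tn)) / (n_pos*n_neg).  The SE uses
    Q1 = A/(2-A), Q2 = 2A^2/(1+A).
    """
    n_pos, n_neg = t.n_pos, t.n_neg
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined without both positive and negative cases")
    a = (t.tp * t.tn + 0.5 * (t.tp * t.fp + t.fn * t.tn)) / (n_pos * n_neg)
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    se = math.sqrt(max(var, 0.0))
    z = 1.96
    ci = (max(0.0, a - z * se), min(1.0, a + z * se))
    return AurocResult(auc=a, se=se, ci95=ci, n_pos=n_pos, n_neg=n_neg, q1=q1, q2=q2)


def contingency_from_cohort(
    summaries: Sequence[EncounterSummary], truth: dict[str, bool]
) -> ContingencyTable:
    """Cross encounter-level screen results against ground-truth labels.

    Screen-positive = the engine raised >=1 possible-ARDS event during the
    encounter; truth maps encounter_id -> gold-standard ARDS status.
    """
    tp = fp = fn = tn = 0
    for s in summaries:
        if s.encounter_id not in truth:
            continue
        screen = s.n_possible_ards_events > 0
        gold = truth[s.encounter_id]
        if screen and gold:
            tp += 1
        elif screen and not gold:
            fp += 1
        elif not screen and gold:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# report tables

_REC_ORDER = [
    RecommendationType.protocols_not_ordered,
    RecommendationType.cpap_ps_inappropriate,
    RecommendationType.change_to_volume_control,
    RecommendationType.nonstandard_mode,
    RecommendationType.ventilation_protocol_not_ordered,
    RecommendationType.noncompliant_mode,
    RecommendationType.oxygenation_protocol_not_ordered,
    RecommendationType.peep_fio2_inappropriate,
    RecommendationType.tidal_volume_too_large,
]


def adherence_table(summaries: Sequence[EncounterSummary]) -> pd.DataFrame:
    """Per-recommendation adherence table with category subtotals and a total.

    Columns: recommendation, category, sent, pct_of_total, followed,
    pct_adherent.  Percentages are half-up rounded to 1 decimal, matching
    report rendering.
    """
    sent = Counter()
    followed = Counter()
    for s in summaries:
        sent.update(s.rec_sent)
        followed.update(s.rec_followed)
    total_sent = sum(sent.values())
    rows = []

    def row(label, category, s, f):
        rows.append({
            "recommendation": label,
            "category": category,
            "sent": s,
            "pct_of_total": round_half_up(100.0 * s / total_sent, 1) if total_sent else 0.0,
            "followed": f,
            "pct_adherent": round_half_up(100.0 * f / s, 1) if s else 0.0,
        })

    for cat in ("adopt_protocol", "specific_setting"):
        cat_types = [t for t in _REC_ORDER if category_of(t).value == cat]
        for t in cat_types:
            row(t.value, cat, sent.get(t, 0), followed.get(t, 0))
        row(f"subtotal_{cat}", cat,
            sum(sent.get(t, 0) for t in cat_types),
            sum(followed.get(t, 0) for t in cat_types))
    row("total", "all", total_sent, sum(followed.values()))
    return pd.DataFrame(rows)


def site_table(summaries: Sequence[EncounterSummary]) -> pd.DataFrame:
    """Per-site performance table: encounters, nonadherence, alert volume.

    Columns mirror the tool's deployment report: trigger-bearing
    encounters, % with initial nonadherence, alerts sent, alerts per
    nonadherent event, % of potential alerts prevented.
    """
    rows = []
    sites = sorted({s.site_id or "unknown" for s in summaries})
    for site in sites + ["__total__"]:
        group = [
            s for s in summaries
            if site == "__total__" or (s.site_id or "unknown") == site
        ]
        group = [s for s in group if s.n_trigger_events > 0]
        if not group:
            continue
        n_enc = len(group)
        nonadh_enc = sum(1 for s in group if s.n_nonadherent_events > 0)
        alerts = sum(s.n_alerts_sent for s in group)
        possible = sum(s.n_possible_ards_events for s in group)
        nonadherent = sum(s.n_nonadherent_events for s in group)
        per_event = alerts / nonadherent if nonadherent else float("nan")
        prevented, pct_prev = alerts_prevented([(possible, nonadherent, alerts)])
        rows.append({
            "site": "total" if site == "__total__" else site,
            "encounters": n_enc,
            "pct_initial_nonadherence": round_half_up(100.0 * nonadh_enc / n_enc, 1),
            "alerts_sent": alerts,
            "alerts_per_nonadherent_event": round_half_up(per_event, 1)
            if nonadherent else None,
            "pct_alerts_prevented": round_half_up(pct_prev, 1),
        })
    return pd.DataFrame(rows)


def evaluate_cohort(
    ledgers: dict[str, EncounterLedger],
    cfg: EngineConfig,
    truth: Optional[dict[str, bool]] = None,
) -> dict:
    """Full service-outcome summary for a cohort of engine ledgers.

    Returns a JSON-serializable dict: initial nonadherence, recommendation
    adherence overall and by category, alert volume, alerts prevented
    (site-stratified), and — when ground-truth labels are supplied — the
    screening contingency metrics and Hanley–McNeil AUROC.
    """
    summaries = [summarize_encounter(ledger, cfg) for ledger in ledgers.values()]
    eligible = [s for s in summaries if s.n_trigger_events > 0]
    sent = Counter()
    followed = Counter()
    for s in summaries:
        sent.update(s.rec_sent)
        followed.update(s.rec_followed)

    def cat_counts(cat):
        types = [t for t in _REC_ORDER if category_of(t).value == cat]
        return (sum(sent.get(t, 0) for t in types), sum(followed.get(t, 0) for t in types))

    adopt_sent, adopt_followed = cat_counts("adopt_protocol")
    spec_sent, spec_followed = cat_counts("specific_setting")
    total_sent, total_followed = sum(sent.values()), sum(followed.values())

    n_alerts = sum(s.n_alerts_sent for s in summaries)
    n_nonadherent_events = sum(s.n_nonadherent_events for s in summaries)
    per_site: dict[str, list[int]] = {}
    for s in summaries:
        acc = per_site.setdefault(s.site_id or "unknown", [0, 0, 0])
        acc[0] += s.n_possible_ards_events
        acc[1] += s.n_nonadherent_events
        acc[2] += s.n_alerts_sent
    prevented, pct_prevented = alerts_prevented([tuple(v) for v in per_site.values()])

    out = {
        "n_encounters_with_trigger": len(eligible),
        "n_trigger_events": sum(s.n_trigger_events for s in summaries),
        "n_possible_ards_events": sum(s.n_possible_ards_events for s in summaries),
        "n_nonadherent_events": n_nonadherent_events,
        "n_alerts_sent": n_alerts,
        "initial_nonadherence": initial_nonadherence(summaries) if eligible else None,
        "mean_alerts_per_nonadherent_event": (
            mean_alerts_per_event(n_alerts, n_nonadherent_events)
            if n_nonadherent_events else None
        ),
        "alerts_prevented": prevented,
        "pct_alerts_prevented": pct_prevented,
        "recommendations": {
            "total": {"sent": total_sent, "followed": total_followed},
            "adopt_protocol": {"sent": adopt_sent, "followed": adopt_followed},
            "specific_setting": {"sent": spec_sent, "followed": spec_followed},
            "by_type": {
                t.value: {"sent": sent.get(t, 0), "followed": followed.get(t, 0)}
                for t in _REC_ORDER
            },
        },
    }
    if total_sent:
        out["recommendation_adherence"] = recommendation_adherence(total_followed, total_sent)
    if adopt_sent:
        out["adopt_protocol_adherence"] = recommendation_adherence(adopt_followed, adopt_sent)
    if spec_sent:
        out["specific_setting_adherence"] = recommendation_adherence(spec_followed, spec_sent)
    if truth is not None:
        table = contingency_from_cohort(summaries, truth)
        out["accuracy"] = {
            "contingency": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
            "metrics": contingency_metrics(table),
            "auroc": auroc_hanley_mcneil(table).__dict__
            if table.n_pos and table.n_neg else None,
        }
    return out
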