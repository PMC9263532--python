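# Methods

This note documents the modeling and design choices behind `ardsalert`:
what each component assumes, which parameters matter and why their
defaults are what they are, what the synthetic cohort generator does and
does not emulate, and the numerical conventions used throughout.

## Screening model

The possible-ARDS screen applies two of the four Berlin-style criteria:
bilateral infiltrates on the chest radiograph report and qualifying
hypoxemia measured as the PaO₂/FiO₂ (P/F) ratio. It is deliberately an
*incomplete* disease-detection system: its purpose is to gate treatment
advice, not to diagnose.

**P/F pairing.** A newly charted PaO₂ pairs with the most recent FiO₂
charted at or before it; a new radiograph triggers with the most recent
derived P/F pair. This most-recent-at-or-before convention is the standard
way EHR rules join asynchronously charted observations. If no FiO₂ (or no
blood gas, for a radiograph) exists yet, no physiology is computable and
no trigger is emitted.

**Altitude adjustment.** The adjusted ratio scales by
`760 / barometric_pressure` (mmHg). The default barometric pressure is
760, i.e. no adjustment: the 255 mmHg threshold is itself an
altitude-adjusted form of the conventional 300 mmHg cutoff
(255 ≈ 300 × 646/760, the pressure of a high-altitude deployment), so
applying a second correction by default would double-count. Sites at
altitude can set their pressure explicitly.

**Threshold comparison.** Qualification is `adjusted P/F ≤ 255` —
inclusive. Where prose and tabular statements of such rules disagree on
strictness, the tabulated operational logic is taken as normative.

**Windows in hours.** "Charted < 7 days ago" and "intubated within the
last 4 days" are enforced as strict hour windows (< 168 h, ≤ 96 h) from
the event timestamp. Calendar-day arithmetic is ambiguous across time
zones; all internal timestamps are UTC and serialized ISO-8601 with an
explicit offset for the same reason — the 16-h and 2-h windows below must
be unambiguous.

**Re-qualification.** The P/F criterion is checked again at
treatment-detection time (it appears independently in both the trigger
and LPV-detection logic), so a stale trigger cannot generate advice after
oxygenation improves.

## Infiltrate classifier

The production systems this models use a proprietary NLP model whose
internals are not public. Here the classifier is a deterministic,
auditable rule matcher behind a pluggable interface (`DetectionResult` is
the only downstream contract, so a statistical model can be substituted):

* clauses split on `. ; :`; tokens are alphanumeric runs, lowercased;
* a finding term (infiltrate/opacity/opacification/consolidation/airspace)
  matches when a laterality cue (bilateral, bilaterally, bibasilar,
  biapical, both) or a paired right-and-left construction lies within 6
  tokens in the same clause;
* negation cues claim a forward scope of 5 tokens (post-negation cues such
  as "resolved" claim a backward scope), terminated early by contrastive
  conjunctions ("but", "however", …);
* hedging ("possible", "cannot exclude", "concerning for") is treated as
  positive: the tool screens for *possible* ARDS and prefers sensitivity
  over precision.

The classifier is validated by exact agreement with a hand-labeled,
balanced 64-report templated corpus shipped in the package
(`data/report_corpus.tsv`: affirmed / negated / clear / hedged families).
Any measured sensitivity or predictive value of this stand-in is a
property of the stand-in and the templated language only; no field
performance is claimed, and the corpus cannot represent the variability of
real radiology prose.

## Treatment (LPV) detection

Nine recommendation types, in two categories:

| category | types |
|---|---|
| adopt-protocol (7) | both protocols not ordered; ventilation protocol not ordered; oxygenation protocol not ordered; CPAP/PS inappropriate; change to volume control; nonstandard mode; noncompliant mode |
| specific-setting (2) | inappropriate PEEP/FiO₂ combination; tidal volume too large |

**Gating.** Specific-setting checks run only when the corresponding
protocol has been ordered: a patient with no protocols gets the adoption
recommendation, not a setting critique, because the setting instructions
come from the protocols themselves. This mirrors the reported split of
recommendations between adopters and non-adopters. A consequence is that
a single assessment never mixes "order the protocol" with a setting
critique for the *same* protocol; multi-recommendation events arise from
combinations such as a missing oxygenation order plus an inappropriate
CPAP/PS configuration.

**Tidal volume.** Limit 6.5 mL/kg predicted body weight, strict
inequality, configurable. 6.5 is the conventional low-tidal-volume
adherence bound; the deployed cutoff is not published. PBW uses the Devine
formulas (male `50 + 0.91·(h − 152.4)`, female `45.5 + 0.91·(h − 152.4)`,
h in cm), floored at 20 kg, defined only for heights in [120, 230] cm.
When sex or height is uncharted the check is skipped and flagged — PBW is
never guessed.

**PEEP/FiO₂ grids.** The shipped defaults reproduce the public ARDSNet
lower- and higher-PEEP co-titration tables as editable YAML. Lookup takes
the nearest grid FiO₂ level *not above* the charted FiO₂ (falling back to
the lowest level under 0.30) and accepts a PEEP within ±1 cmH₂O of any
allowed value. The deployed grid content is protocol-internal; the check
structure, not the cell values, is the contract here.

**Mode policy.** CPAP/PS is inappropriate when PEEP > 10 cmH₂O, or
FiO₂ > 0.50, or pressure support > 15 cmH₂O (strict comparisons).
Otherwise modes are judged against two configurable sets: modes outside
`standard_modes` draw the nonstandard-mode recommendation; standard but
non-`compliant_modes` draw the noncompliant-mode recommendation; a
compliant non-volume-control mode draws the "consider volume control"
suggestion. The defaults (standard = volume control, pressure control,
SIMV, CPAP/PS; compliant = volume control, pressure control, CPAP/PS) are
one reasonable taxonomy — the published material distinguishes the three
recommendations without defining the mode sets, so they are configuration,
not fixed rules.

## Alert lifecycle

* Delivery is synchronous on chart open, restricted to treating physicians
  and advanced practice providers (role on the chart-open event).
* The 16-h per-clinician rate limit is a **rolling window from the last
  delivery**, not anchored to shift clock times: "once per shift" is
  operationalized as "every 16 h", and rolling windows are deterministic
  without a shift calendar.
* A chart-close reminder (at most one per alert) fires when any delivered
  recommendation is unaddressed since chart open. "Addressed" means the
  clinician responded to the alert, or a charted change consistent with
  the recommendation occurred in the session — the same consistency rule
  as the followed metric below.
* "Not ARDS" and contraindication responses permanently suppress alerts
  for the patient; the suppression is absorbing for the remainder of the
  encounter. Whether it should persist across separate hospital encounters
  of the same patient is not specified anywhere; it is implemented
  per-encounter, which is the conservative (more-alerting) choice.
* New biomedical data re-evokes the cycle: a fresh nonadherent assessment
  replaces the pending alert content, and an adherent reassessment clears
  it.

## Service outcomes

* **Initial guideline nonadherence** counts *encounters* (≥ 1 nonadherent
  possible-ARDS event) over encounters with ≥ 1 fired trigger.
* **Followed** means a consistent change within `adherence_window_minutes`
  (default 120) after alert delivery: the missing order(s) placed for
  order-type recommendations (the combined type needs both), settings
  moved into compliance for setting-type ones. The window is configurable
  because the underlying definition is hedged ("usually within 2 h").
* **Alerts prevented** is computed per site and summed:
  `(possible − nonadherent) × alerts/nonadherent`; a site with no
  nonadherent events has no observed alerting rate and contributes zero.
  The percentage denominator is prevented + actually sent.
* **Binomial CIs**: both Wald and Clopper–Pearson exact are available
  (via `statsmodels.proportion_confint`), and reports label which was
  used — published survey intervals in this literature often match Wald
  arithmetic even when described as exact.
* **Two-proportion comparison**: Wald difference CI and z-test; a
  degenerate zero SE (both proportions at a boundary) falls back to a
  continuity-corrected SE using `(k+0.5)/(n+1)`.
* **AUROC** for a single-threshold screen uses the tie-credit closed form
  `(TP·TN + 0.5·(TP·FP + FN·TN))/(n₊·n₋)` — provably equal to the
  exhaustive pairwise comparison, which the test suite verifies for every
  contingency table with total ≤ 40 — with the Hanley–McNeil standard
  error. Note that a two-point ROC has no threshold sweep: published AUROC
  values computed from a richer score may legitimately differ from the
  binary-screen closed form on the same 2×2 table.
* Report rendering rounds half-up at the printed precision (1 decimal for
  tables, whole percent for prose).

## Synthetic cohort generator

The generator emulates the *charting surface* of an ICU encounter, not
physiology: values are sampled to satisfy or violate the screening
thresholds. Per trigger-bearing encounter it plants, marginally:

| parameter | default | meaning |
|---|---|---|
| `p_nonadherent` | 0.38 | encounter has ≥ 1 initially nonadherent possible-ARDS episode |
| `p_possible_ards` | 0.60 | encounter develops a possible-ARDS picture at all |
| `p_follow_specific` | 0.65 | a specific-setting recommendation is followed in-window |
| `p_follow_adopt` | 0.14 | an adopt-protocol recommendation is followed in-window |
| `mean_triggers_per_encounter` | 1.5 | additional qualifying blood gases (Poisson) |

The first four defaults are the observed deployment rates; the trigger
intensity matches the reported ratio of trigger events to encounters.
`p_possible_ards` and `p_nonadherent` are both **marginal** rates over
trigger-bearing encounters (`p_nonadherent ≤ p_possible_ards`), so the
engine-measured initial nonadherence estimates `p_nonadherent` directly —
the planted rate is the estimand, with no conditional-probability
conversion. Clinician change times straddle the 120-min window boundary:
followed recommendations resolve at U(5, 115) min after delivery, and half
of the not-followed ones resolve late at U(125, 180) min (the rest never),
so the window boundary is genuinely exercised in both directions within an
overall 5–180 min response range.

Ground truth (planted labels, scenarios, follow decisions) is written to a
sidecar file the engine never reads. Site labels follow a configurable
weight distribution shaped like a hub-and-spoke hospital system.

**What passing tests show — and don't.** Parameter recovery on this
generator demonstrates that the engine + estimators are consistent and
unbiased under the planted mechanism. It does not validate the classifier
against real radiology text (templated language is exact-matchable), nor
the adherence rules against real ventilator charting (settings are planted
cleanly on or off the grid), nor any clinical outcome.

## Numerical and degenerate-input conventions

* FiO₂ values above 1 are interpreted as percent and divided by 100;
  results outside [0.21, 1.0] are rejected, never clamped silently.
* Event order within an encounter is the strict total order
  `(timestamp, event_id)`; parsing is independent of input record order,
  duplicate event ids are rejected, and canonical serialization is
  idempotent (`write(parse(x))` is a fixed point).
* Undefined estimands (zero denominators: no eligible encounters, no
  recommendations, an empty contingency margin) raise or are flagged
  `None`; they are never reported as 0.
* Grid and threshold comparisons carry a 1e-9 tolerance so charted values
  that are exactly at a boundary are classified stably across float
  round-trips.
* Engine state is per-encounter only; encounters are independent, so
  streams can be processed in any encounter order and results are
  deterministic for a fixed seed and config.

## Problem sizes used in validation

The test suite replays 10,000 randomized short encounter streams for the
rate-limit and absorbing-suppression properties, 300 randomized streams of
up to 50 events for the brute-force screening oracle, every contingency
table with total ≤ 40 for the AUROC oracle, and one 2000-encounter
synthetic cohort (fixed seed) for planted-parameter recovery at a 3
binomial-SE tolerance. The acceptance script uses the same 2000-encounter
cohort size. These sizes give stable Monte-Carlo behavior while keeping a
full run inside a few seconds.

## Known limitations

* The infiltrate classifier is a lexicon matcher; real radiology prose
  (section headers, comparisons across studies, templated impressions)
  will defeat it in ways the templated corpus cannot reveal.
* The 39 distinct alert-code bundles of the deployed tool are not
  reproduced; the nine recommendation types are the catalogue here, and
  alert messages bundle whatever recommendations the assessment produced.
* Weaning-assessment and spontaneous-breathing-trial subprotocols are not
  adherence-checked — no rule content for them is published.
* Per-site alerting variation, clinician staffing patterns, and repeat
  encounters of one patient are not modeled by the generator.
* No HL7/FHIR ingestion; the JSONL/CSV stream schema is the only input.
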