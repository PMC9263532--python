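# ardsalert

A desk-scale, testable re-implementation of a clinical decision support
(CDS) alert engine for **possible acute respiratory distress syndrome
(ARDS) not receiving lung-protective ventilation (LPV)** — the kind of
rule-based "sniffer" that runs inside an ICU electronic health record and
interrupts a clinician only when (a) the patient screens positive for
possible ARDS *and* (b) the current ventilator management deviates from
the computerized ventilation/oxygenation protocols.

It is written for critical-care informaticists and implementation
researchers who want to study trigger logic, alert-fatigue suppression
policies, and service-outcome statistics without access to a production
EHR: the package ships a seeded synthetic ICU event-stream generator, so
every component is exercisable offline and deterministically.

## What the engine does

Each charting event in an encounter stream is processed in order through a
four-step cycle:

1. **Trigger** — a newly charted PaO₂ or a new chest X-ray raises a
   trigger event. It *fires* only if all inclusion criteria hold (age ≥ 18;
   ventilator mode charted < 7 days ago; altitude-adjusted
   PaO₂/FiO₂ ≤ 255 mmHg; intubated within the last 4 days) and no
   exclusion applies (PICU, palliative care, cardiothoracic attending,
   mechanical circulatory support, T-piece/trach-mask breathing, pulmonary
   artery catheter).
2. **Disease detection** — the chest-radiograph report text is classified
   for bilateral infiltrates by a deterministic negation-aware rule
   matcher (a pluggable stand-in for a statistical NLP model; hedged
   findings count positive, erring toward sensitivity).
3. **LPV treatment detection** — current treatment is checked against the
   computerized protocols: protocol orders present, ventilator mode
   policy, tidal volume ≤ 6.5 mL/kg predicted body weight (Devine), and
   the PEEP/FiO₂ pair on the configured co-titration grid. Nine typed
   recommendations exist, split into 7 *adopt-protocol* and 2
   *specific-setting* types.
4. **Alert lifecycle** — a nonadherent possible-ARDS event is delivered to
   treating physicians/APPs on chart open, at most once per 16 h per
   clinician, with a chart-close reminder for unaddressed recommendations;
   a "not ARDS" or contraindication response permanently suppresses alerts
   for the patient.

The service-metrics layer computes the evaluation statistics such tools
are judged by: initial guideline nonadherence (nonadherent encounters /
trigger-bearing encounters), recommendation adherence (consistent change
within 2 h of delivery), alerts prevented by the treatment-detection gate
(per site, `(possible − nonadherent) × alerts/nonadherent`), binomial
confidence intervals (Wald and Clopper–Pearson), a two-proportion z
comparison, and a nonparametric AUROC with the Hanley–McNeil standard
error, where for a single-threshold screen

```
A  = (TP·TN + 0.5·(TP·FP + FN·TN)) / (n₊·n₋)
SE = sqrt[(A(1−A) + (n₊−1)(Q₁−A²) + (n₋−1)(Q₂−A²)) / (n₊·n₋)],
     Q₁ = A/(2−A),  Q₂ = 2A²/(1+A)
```

## Worked example

`examples/simulate_and_evaluate.py` generates a 500-encounter synthetic
cohort with the default planted rates, replays it through the engine, and
prints:

```
encounters with >=1 trigger:    500
trigger events:                 756
possible-ARDS events:           458
nonadherent events:             217
alerts sent:                    189
initial nonadherence:           0.378  (planted 0.38)
specific-setting follow rate:   0.640  (planted 0.65)
adopt-protocol follow rate:     0.205  (planted 0.14)
alerts prevented by LPV gate:   210 (53%)
screen vs sidecar truth:        tp=295 fp=0 fn=0 tn=205
```

The engine-measured initial nonadherence and follow rates estimate the
generator's planted parameters; deviations are binomial sampling error at
this cohort size. The zero off-diagonal cells reflect that the rule-based
classifier is exact on the generator's templated report language — a
property of the stand-in, not a claim about field performance.

Other examples: `screen_single_encounter.py` (step-by-step trigger →
recommendation → alert trace), `classify_reports.py` (negation-aware
report matching with matched/negated spans), `published_arithmetic.py`
(service-outcome arithmetic on published deployment counts).

## Command line

```bash
ardsalert simulate --n 500 --seed 42 --out cohort/          # stream + truth sidecar
ardsalert run      --stream cohort/stream.jsonl --out ledgers/
ardsalert evaluate --stream cohort/stream.jsonl \
                   --truth cohort/truth.jsonl --out report/
```

Exit codes: 0 success, 2 validation failure, 3 I/O failure. Every run
writes a `manifest.json` (config hash, seed, paths, version, timing).

## Event-stream format

One JSON object per line; canonical field order and ISO-8601 UTC
timestamps (an equivalent long-format CSV is supported via
`ardsalert.events.read_event_stream_csv`):

```json
{"schema": "1", "encounter_id": "E00001", "event_id": 4,
 "timestamp": "2020-01-01T01:00:00Z",
 "payload": {"type": "blood_gas", "pao2": 84.0}}
```

Payload types: `patient_attrs`, `blood_gas`, `vent_settings`,
`radiograph_report`, `protocol_order`, `chart_open`, `chart_close`,
`clinician_response`. FiO₂ accepts both fraction (0.45) and percent (45)
dialects; values above 1 are treated as percent.

## Layout

```
src/ardsalert/
  events.py       event-stream schema, parsing, JSONL/CSV round-trips
  config.py       thresholds, windows, mode policy, PEEP/FiO2 grids (YAML)
  triggers.py     trigger detection, inclusion/exclusion screening
  infiltrates.py  negation-aware bilateral-infiltrate rule matcher
  adherence.py    LPV treatment detection, 9-type recommendation taxonomy
  alerts.py       delivery, 16-h window, reminders, permanent suppression
  engine.py       single-pass orchestration, audit ledgers
  metrics.py      service outcomes, CIs, contingency metrics, AUROC
  simulate.py     seeded synthetic cohort generator + ground-truth sidecar
  cli.py          simulate / run / evaluate subcommands
  data/           default lexicon, PEEP/FiO2 grids, labeled report corpus
```

See `docs/methods.md` for the modeling assumptions, parameter defaults,
and known limitations.
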