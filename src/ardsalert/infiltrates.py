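"""Bilateral-infiltrate detection on chest-radiograph report text.

This is a deterministic, auditable rule-based classifier standing behind a
pluggable interface: the alert engine depends only on
:class:`DetectionResult`, so any substitute classifier (e.g. a statistical
model) can be dropped in.  The matcher is a small NegEx-style scheme:

* tokenize each clause (clauses split on ``. ; :``);
* a *finding* term (infiltrate/opacity/consolidation/airspace ...) matches
  when a *laterality* cue (bilateral/bibasilar/both ...) or a paired
  right-and-left construction sits within a token window of it;
* negation cues claim a scope of following (or, for post-negation cues like
  "resolved", preceding) tokens, terminated early by conjunctions such as
  "but"; a match whose finding token falls inside a scope is negated;
* hedging language ("possible", "cannot exclude") is deliberately treated
  as positive — the tool screens for *possible* ARDS and errs toward
  sensitivity.

The classifier is validated against a hand-labeled templated report corpus
shipped with the package (``data/report_corpus.tsv``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Optional, Protocol

import yaml
from pydantic import BaseModel, Field

from .events import RadiographReport

_TOKEN_RE = re.compile(r"[A-Za-z0-9']+")
_CLAUSE_SPLIT_RE = re.compile(r"[.;:]")


@dataclass(frozen=True)
class Span:
    start: int  # character offsets into the report text
    end: int

    def as_tuple(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of classifying one report; consumed downstream as-is."""

    positive: bool
    matched_spans: tuple[tuple[str, tuple[int, int]], ...] = ()
    negated_spans: tuple[tuple[int, int], ...] = ()


class InfiltrateClassifier(Protocol):
    """Anything that maps a radiograph report to a DetectionResult."""

    def __call__(self, report: RadiographReport) -> DetectionResult: ...


class NegationCue(BaseModel):
    cue: str
    scope: int = Field(ge=1, description="scope length in tokens")
    direction: Literal["forward", "backward"] = "forward"

    @property
    def tokens(self) -> list[str]:
        return self.cue.lower().split()


class RuleSet(BaseModel):
    """Compiled lexicon for the rule-based matcher; loaded from YAML."""

    laterality_terms: list[str]
    laterality_pairs: list[tuple[str, str]] = Field(default_factory=list)
    finding_terms: list[str]
    pair_window: int = Field(default=6, ge=1)
    negation_cues: list[NegationCue]
    scope_terminators: list[str] = Field(default_factory=list)
    uncertainty_cues: list[str] = Field(default_factory=list)
    uncertainty_polarity: Literal["positive", "negative"] = "positive"

    @classmethod
    def default(cls) -> "RuleSet":
        text = resources.files("ardsalert.data").joinpath("infiltrate_lexicon.yaml").read_text()
        return cls.model_validate(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path) -> "RuleSet":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def _tokenize(text: str, offset: int) -> list[tuple[str, Span]]:
    return [
        (m.group(0).lower(), Span(offset + m.start(), offset + m.end()))
        for m in _TOKEN_RE.finditer(text)
    ]


def _clauses(text: str) -> list[tuple[str, int]]:
    clauses, pos = [], 0
    for m in _CLAUSE_SPLIT_RE.finditer(text):
        clauses.append((text[pos:m.start()], pos))
        pos = m.end()
    clauses.append((text[pos:], pos))
    return [(c, off) for c, off in clauses if c.strip()]


def apply_negation_scopes(
    tokens: list[str], cues: list[NegationCue], terminators: Optional[list[str]] = None
) -> set[int]:
    """Token indices claimed by any negation cue.

    A forward cue negates up to ``scope`` tokens after it; a backward cue
    (post-negation, e.g. "resolved") claims tokens before it.  A scope ends
    early at a terminator token ("but", "however", ...).
    """
    terminators = set(t.lower() for t in (terminators or []))
    negated: set[int] = set()
    n = len(tokens)
    for cue in cues:
        ct = cue.tokens
        for i in range(n - len(ct) + 1):
            if tokens[i : i + len(ct)] != ct:
                continue
            if cue.direction == "forward":
                j = i + len(ct)
                for k in range(j, min(j + cue.scope, n)):
                    if tokens[k] in terminators:
                        break
                    negated.add(k)
            else:
                for k in range(i - 1, max(i - 1 - cue.scope, -1), -1):
                    if tokens[k] in terminators:
                        break
                    negated.add(k)
    return negated


class RuleBasedDetector:
    """Default classifier: lexicon matching with negation scoping."""

    def __init__(self, rules: Optional[RuleSet] = None):
        self.rules = rules or RuleSet.default()

    def __call__(self, report: RadiographReport) -> DetectionResult:
        return detect_bilateral_infiltrates(report, self.rules)


def detect_bilateral_infiltrates(
    report: RadiographReport, rules: Optional[RuleSet] = None
) -> DetectionResult:
    """Classify a report as positive/negative for bilateral infiltrates.

    Deterministic; an empty report is negative.  Both positive and negative
    results flow downstream — negatives matter for audit and accuracy
    statistics.
    """
    rules = rules or RuleSet.default()
    text = report.report_text or ""
    laterality = set(rules.laterality_terms)
    findings = set(rules.finding_terms)
    matched: list[tuple[str, tuple[int, int]]] = []
    negated: list[tuple[int, int]] = []
    any_positive = False

    for clause, offset in _clauses(text):
        toks = _tokenize(clause, offset)
        words = [w for w, _ in toks]
        scopes = apply_negation_scopes(words, rules.negation_cues, rules.scope_terminators)
        for i, (w, span) in enumerate(toks):
            if w not in findings:
                continue
            lo, hi = max(0, i - rules.pair_window), min(len(words), i + rules.pair_window + 1)
            window = words[lo:hi]
            lat_hit = any(t in laterality for t in window)
            pair_hit = any(a in window and b in window for a, b in rules.laterality_pairs)
            if not (lat_hit or pair_hit):
                continue
            pattern_id = f"{'paired_laterality' if not lat_hit else 'laterality'}+{w}"
            if i in scopes:
                negated.append(span.as_tuple())
            else:
                matched.append((pattern_id, span.as_tuple()))
                any_positive = True

    return DetectionResult(
        positive=any_positive,
        matched_spans=tuple(matched),
        negated_spans=tuple(negated),
    )
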