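# Default lexicon for the rule-based bilateral-infiltrate classifier.
# A report is positive when a finding term co-occurs with a laterality cue
# (or a paired right/left construction) within `pair_window` tokens of the
# same clause, and the finding token is not inside a negation scope.
laterality_terms: [bilateral, bilaterally, bibasilar, biapical, both]
laterality_pairs:
  - [right, left]
  - [left, right]
finding_terms:
  - infiltrate
  - infiltrates
  - opacity
  - opacities
  - opacification
  - opacifications
  - consolidation
  - consolidations
  - airspace
pair_window: 6
negation_cues:
  - {cue: "no", scope: 5}
  - {cue: "not", scope: 5}
  - {cue: "without", scope: 5}
  - {cue: "negative for", scope: 5}
  - {cue: "free of", scope: 5}
  - {cue: "clear of", scope: 5}
  - {cue: "absence of", scope: 5}
  - {cue: "resolution of", scope: 5}
  - {cue: "clearing of", scope: 5}
  - {cue: "resolved", scope: 5, direction: backward}
  - {cue: "cleared", scope: 5, direction: backward}
scope_terminators: [but, however, although, though, yet, aside]
# The tool screens for *possible* ARDS: hedged findings still alert.
uncertainty_cues:
  - possible
  - possibly
  - probable
  - likely
  - suspicious for
  - concerning for
  - cannot exclude
  - may represent
  - suggestive of
uncertainty_polarity: positive
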