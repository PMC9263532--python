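"""Classify chest-radiograph report text for bilateral infiltrates.

Shows the negation-aware rule matcher on affirmed, negated and hedged
language.  "positive" means the report supports the possible-ARDS screen;
hedged findings ("possible", "cannot exclude") are deliberately positive
because the tool errs toward sensitivity.
"""

from ardsalert import detect_bilateral_infiltrates
from ardsalert.events import RadiographReport

REPORTS = [
    "Diffuse bilateral infiltrates consistent with edema.",
    "No focal infiltrate; lungs clear bilaterally.",
    "No fracture but bilateral infiltrates at the bases.",
    "Cannot exclude early bilateral consolidation.",
    "The previously noted bilateral opacities have resolved.",
    "Patchy opacities in the right and left lower lobes.",
]

for text in REPORTS:
    result = detect_bilateral_infiltrates(RadiographReport(report_text=text))
    tag = "POSITIVE" if result.positive else "negative"
    print(f"{tag}  {text}")
    for pattern_id, (start, end) in result.matched_spans:
        print(f"          matched {pattern_id!r} -> {text[start:end]!r}")
    for start, end in result.negated_spans:
        print(f"          negated span -> {text[start:end]!r}")
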