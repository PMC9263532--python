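"""Service-outcome arithmetic on the deployed tool's printed counts.

Feeds the published recommendation counts (3281 recommendations, 1566
followed) through the package's estimators: adherence percentages by
category, the between-category proportion difference with its Wald 95% CI,
the alerts-per-event ratio, and the screening accuracy statistics for the
reconstructed 73-patient validation table (including the Hanley–McNeil
AUROC standard error for a single-threshold screen).
"""

from ardsalert.metrics import (
    ContingencyTable,
    auroc_hanley_mcneil,
    contingency_metrics,
    mean_alerts_per_event,
    proportion_difference_ci,
    recommendation_adherence,
    round_half_up,
)

adopt_sent, adopt_followed = 1119, 156
specific_sent, specific_followed = 2162, 1410
total_sent, total_followed = adopt_sent + specific_sent, adopt_followed + specific_followed

pct = lambda f, s: round_half_up(100 * recommendation_adherence(f, s), 1)  # noqa: E731
print(f"overall adherence:          {pct(total_followed, total_sent)}%  ({total_followed}/{total_sent})")
print(f"adopt-protocol adherence:   {pct(adopt_followed, adopt_sent)}%  ({adopt_followed}/{adopt_sent})")
print(f"specific-setting adherence: {pct(specific_followed, specific_sent)}%  ({specific_followed}/{specific_sent})")

diff, (lo, hi), p = proportion_difference_ci(adopt_followed, adopt_sent,
                                             specific_followed, specific_sent)
print(f"category difference:        {diff:.2f} [95% CI {lo:.2f}-{hi:.2f}], p={p:.2g}")
print(f"alerts per nonadherent event: {round_half_up(mean_alerts_per_event(2876, 455), 1)}")

table = ContingencyTable(tp=35, fp=22, fn=5, tn=11)
m = contingency_metrics(table)
roc = auroc_hanley_mcneil(table)
print(f"screen accuracy:            {m['accuracy']['value']:.2f}")
print(f"screen sensitivity:         {m['sensitivity']['value']:.2f}")
print(f"screen PPV:                 {m['ppv']['value']:.2f}")
print(f"screen FPR:                 {m['fpr']['value']:.2f}")
print(f"AUROC (tie-credit):         {roc.auc:.3f} +/- {roc.se:.3f} "
      f"[95% CI {roc.ci95[0]:.2f}-{roc.ci95[1]:.2f}]")
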