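"""Composite-score accuracy and paired agreement with the MMC.

Computes the composite 2x2, the five headline accuracy indices with
Wilson CIs, the McNemar test on the discordant cells, Cohen's kappa, and
both Cohen's g variants.
"""

import json
from pathlib import Path

from airwayscore import (
    agreement_summary,
    build_contingency,
    compute_metrics,
    mmc_reference,
    read_cohort_csv,
    score_record,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_cohort_csv(RESULTS / "cohort.csv")
    references = [mmc_reference(r.mmc_class) for r in records]
    table = build_contingency([score_record(r).positive for r in records], references)
    m = compute_metrics(table)
    agree = agreement_summary(table)

    print(f"composite 2x2 (tp, fp, fn, tn): {table.as_tuple()}")
    for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
        est = getattr(m, name)
        print(f"{name:>12}: {est.percent:6.2f}%  (95% CI {100*est.ci_low:.2f}-{100*est.ci_high:.2f})")
    print(f"  prevalence: {m.prevalence.percent:6.2f}%")
    print(
        f"McNemar chi2={agree.mcnemar.chi2:.2f} (df=1, uncorrected), p={agree.mcnemar.p_value:.3f}"
    )
    print(f"kappa={agree.kappa:.3f}")
    print(
        f"Cohen's g: classic={agree.g_classic.value:.3f}, "
        f"marginal difference |b-c|/n={agree.g_marginal_difference.value:.3f}"
    )

    doc = {
        "table": dict(zip(("tp", "fp", "fn", "tn"), table.as_tuple())),
        "metrics_pct": {
            name: getattr(m, name).percent
            for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "prevalence")
        },
        "mcnemar": {"chi2": agree.mcnemar.chi2, "df": 1, "p": agree.mcnemar.p_value},
        "kappa": agree.kappa,
        "cohens_g_classic": agree.g_classic.value,
        "cohens_g_marginal_difference": agree.g_marginal_difference.value,
    }
    out = RESULTS / "composite_agreement.json"
    out.write_text(json.dumps(doc, indent=2) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
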