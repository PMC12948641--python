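"""Reproduction harness: recompute every published statistic and diff-check it.

The bundled expectations table lists each printed statistic with its
printed precision.  ``reproduce`` reconstructs the cohort from the
printed margins, runs the full scoring / accuracy / agreement / ROC
pipeline on the patient-level records, and compares each recomputed value
to its printed counterpart at printed precision (half-up rounding).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Sequence

from .agreement import agreement_summary
from .metrics import build_contingency, compute_metrics, round_half_up
from .reconstruct import reconstruct_cohort
from .roc import ScoreDistribution, roc_analysis
from .scoring import (
    DEFAULT_THRESHOLDS,
    PREDICTOR_NAMES,
    PatientAirwayRecord,
    ScoreThresholds,
    evaluate_predictors,
    mmc_reference,
    score_record,
)


@dataclass(frozen=True)
class Expectation:
    stat_id: str
    expected: str
    decimals: int
    source: str


def load_expectations() -> list[Expectation]:
    """The bundled table of printed statistics and their printed precisions."""
    text = resources.files("airwayscore").joinpath("data/expectations.csv").read_text()
    rows = list(csv.DictReader(text.splitlines()))
    return [
        Expectation(r["stat_id"], r["expected"], int(r["decimals"]), r["source"])
        for r in rows
    ]


def compute_study_statistics(
    records: Sequence[PatientAirwayRecord],
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
    continuity: bool = False,
) -> dict[str, float]:
    """Every statistic in the expectations table, recomputed from patient records."""
    references = [mmc_reference(r.mmc_class) for r in records]
    all_flags = [evaluate_predictors(r, thresholds).as_tuple() for r in records]
    scores = [score_record(r, thresholds) for r in records]

    out: dict[str, float] = {}
    for j, name in enumerate(PREDICTOR_NAMES):
        table = build_contingency([f[j] for f in all_flags], references)
        m = compute_metrics(table)
        out[f"{name}.tp"], out[f"{name}.fp"] = table.tp, table.fp
        out[f"{name}.fn"], out[f"{name}.tn"] = table.fn, table.tn
        out[f"{name}.sensitivity_pct"] = m.sensitivity.percent
        out[f"{name}.specificity_pct"] = m.specificity.percent

    composite_table = build_contingency([s.positive for s in scores], references)
    cm = compute_metrics(composite_table)
    out["composite.tp"], out["composite.fp"] = composite_table.tp, composite_table.fp
    out["composite.fn"], out["composite.tn"] = composite_table.fn, composite_table.tn
    out["composite.sensitivity_pct"] = cm.sensitivity.percent
    out["composite.specificity_pct"] = cm.specificity.percent
    out["composite.ppv_pct"] = cm.ppv.percent
    out["composite.npv_pct"] = cm.npv.percent
    out["composite.accuracy_pct"] = cm.accuracy.percent
    out["prevalence_pct"] = cm.prevalence.percent

    agree = agreement_summary(composite_table, continuity=continuity)
    out["agreement.mcnemar_chi2"] = agree.mcnemar.chi2
    out["agreement.mcnemar_p"] = agree.mcnemar.p_value
    out["agreement.kappa"] = agree.kappa
    out["agreement.cohens_g_marginal"] = agree.g_marginal_difference.value
    out["agreement.cohens_g_classic"] = agree.g_classic.value

    dist = ScoreDistribution.from_scores([s.score for s in scores], references)
    roc = roc_analysis(dist, thresholds.positivity_threshold)
    out["roc.auc_binary"] = roc.auc_binary
    out["roc.auc_ordinal"] = roc.auc_ordinal
    out["roc.auc_se"] = roc.se
    for row in roc.per_cutoff:
        out[f"cutoff{row.cutoff}.sensitivity_pct"] = 100.0 * row.sensitivity
        out[f"cutoff{row.cutoff}.fpr_pct"] = 100.0 * row.fpr
        out[f"cutoff{row.cutoff}.specificity_pct"] = 100.0 * row.specificity
        out[f"cutoff{row.cutoff}.youden_pct"] = 100.0 * row.youden
    return out


@dataclass(frozen=True)
class ReproductionRow:
    stat_id: str
    expected: str
    computed: float
    computed_at_precision: str
    source: str
    passed: bool


@dataclass(frozen=True)
class ReproductionReport:
    rows: list[ReproductionRow]

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.rows)

    @property
    def failures(self) -> list[ReproductionRow]:
        return [r for r in self.rows if not r.passed]

    def as_dicts(self) -> list[dict]:
        return [asdict(r) for r in self.rows]


def compare_to_expectations(computed: dict[str, float]) -> ReproductionReport:
    """Diff each recomputed statistic against its printed value at printed precision."""
    rows = []
    for exp in load_expectations():
        value = computed[exp.stat_id]
        formatted = f"{round_half_up(value, exp.decimals):.{exp.decimals}f}"
        target = f"{round_half_up(float(exp.expected), exp.decimals):.{exp.decimals}f}"
        rows.append(
            ReproductionRow(
                stat_id=exp.stat_id,
                expected=target,
                computed=value,
                computed_at_precision=formatted,
                source=exp.source,
                passed=formatted == target,
            )
        )
    return ReproductionReport(rows)


def reproduce(
    seed: int = 0,
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
    continuity: bool = False,
) -> ReproductionReport:
    """Reconstruct the cohort, rerun the full pipeline, diff every printed statistic."""
    records = reconstruct_cohort(seed=seed)
    stats = compute_study_statistics(records, thresholds, continuity=continuity)
    return compare_to_expectations(stats)


def _proportion_entry(est) -> dict | None:
    if est is None:
        return {"undefined": True}
    return {
        "value": est.value,
        "percent": est.percent,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "numerator": est.numerator,
        "denominator": est.denominator,
        "ci_level": est.ci_level,
    }


def evaluation_document(
    records: Sequence[PatientAirwayRecord],
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
    continuity: bool = False,
) -> dict:
    """Full machine-readable evaluation of a cohort (metrics, agreement, ROC)."""
    references = [mmc_reference(r.mmc_class) for r in records]
    if all(references) or not any(references):
        missing = "easy" if all(references) else "difficult"
        raise ValueError(
            f"cohort lacks {missing}-airway patients; specificity or sensitivity undefined"
        )
    all_flags = [evaluate_predictors(r, thresholds).as_tuple() for r in records]
    scores = [score_record(r, thresholds) for r in records]

    def metrics_entry(table) -> dict:
        m = compute_metrics(table)
        return {
            "table": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
            "sensitivity": _proportion_entry(m.sensitivity),
            "specificity": _proportion_entry(m.specificity),
            "ppv": _proportion_entry(m.ppv),
            "npv": _proportion_entry(m.npv),
            "accuracy": _proportion_entry(m.accuracy),
            "prevalence": _proportion_entry(m.prevalence),
        }

    composite_table = build_contingency([s.positive for s in scores], references)
    agree = agreement_summary(composite_table, continuity=continuity)
    dist = ScoreDistribution.from_scores([s.score for s in scores], references)
    roc = roc_analysis(dist, thresholds.positivity_threshold)
    return {
        "n": len(records),
        "per_predictor": {
            name: metrics_entry(build_contingency([f[j] for f in all_flags], references))
            for j, name in enumerate(PREDICTOR_NAMES)
        },
        "composite": metrics_entry(composite_table),
        "agreement": {
            "mcnemar_chi2": agree.mcnemar.chi2,
            "df": agree.mcnemar.df,
            "p_value": agree.mcnemar.p_value,
            "continuity_corrected": agree.mcnemar.continuity_corrected,
            "kappa": agree.kappa,
            "cohens_g_classic": agree.g_classic.value,
            "cohens_g_marginal_difference": agree.g_marginal_difference.value,
        },
        "roc": {
            "points": roc.points,
            "auc_binary_as_published": roc.auc_binary,
            "auc_ordinal_full_curve": roc.auc_ordinal,
            "se_hanley_mcneil": roc.se,
            "ci": roc.ci,
            "per_cutoff": [
                {
                    "cutoff": r.cutoff,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "youden": r.youden,
                }
                for r in roc.per_cutoff
            ],
            "score_counts_difficult": list(dist.counts_difficult),
            "score_counts_easy": list(dist.counts_easy),
        },
    }
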