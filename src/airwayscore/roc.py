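"""Empirical ROC of the ordinal 0-5 score against the binary reference.

Two areas are distinguished deliberately:

* ``trapezoid_auc`` — the full ordinal ROC over cutoffs 6..0, whose area
  equals the pairwise concordance probability (ties counted 1/2);
* ``binary_auc`` — the single-interior-point ROC of the dichotomised
  (score >= 1) classifier, whose area is (sensitivity + specificity)/2.

The two differ whenever the score carries ordinal information beyond the
dichotomy, so both are always reported and labelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .metrics import ContingencyTable2x2, compute_metrics

MAX_SCORE = 5
N_LEVELS = MAX_SCORE + 1


@dataclass(frozen=True)
class ScoreDistribution:
    """Counts of patients at each score 0..5, split by reference group."""

    counts_difficult: tuple[int, ...]
    counts_easy: tuple[int, ...]

    def __post_init__(self) -> None:
        for name in ("counts_difficult", "counts_easy"):
            counts = getattr(self, name)
            if len(counts) != N_LEVELS:
                raise ValueError(f"{name} must have {N_LEVELS} entries (scores 0..{MAX_SCORE})")
            if any((not isinstance(c, (int, np.integer))) or c < 0 for c in counts):
                raise ValueError(f"{name} must be non-negative integers")

    @property
    def n_difficult(self) -> int:
        return int(sum(self.counts_difficult))

    @property
    def n_easy(self) -> int:
        return int(sum(self.counts_easy))

    @classmethod
    def from_scores(
        cls, scores: Sequence[int], references: Sequence[bool | int]
    ) -> "ScoreDistribution":
        if len(scores) != len(references):
            raise ValueError("length mismatch between scores and references")
        difficult = [0] * N_LEVELS
        easy = [0] * N_LEVELS
        for s, r in zip(scores, references):
            (difficult if r else easy)[s] += 1
        return cls(tuple(difficult), tuple(easy))


@dataclass(frozen=True)
class CutoffRow:
    cutoff: int
    sensitivity: float
    specificity: float
    youden: float

    @property
    def fpr(self) -> float:
        return 1.0 - self.specificity


def _check_nondegenerate(dist: ScoreDistribution) -> None:
    if dist.n_difficult == 0 or dist.n_easy == 0:
        raise ValueError("both reference groups must be non-empty")


def cutoff_table(dist: ScoreDistribution) -> list[CutoffRow]:
    """Sensitivity, specificity and Youden index at each integer cutoff 1..5.

    At cutoff c a patient is called positive when score >= c; Youden's
    index is sensitivity + specificity - 1.
    """
    _check_nondegenerate(dist)
    rows = []
    for c in range(1, MAX_SCORE + 1):
        sens = sum(dist.counts_difficult[c:]) / dist.n_difficult
        spec = sum(dist.counts_easy[:c]) / dist.n_easy
        rows.append(CutoffRow(c, sens, spec, sens + spec - 1.0))
    return rows


def roc_points(dist: ScoreDistribution) -> list[tuple[float, float]]:
    """Empirical ROC points (FPR, TPR) from cutoff 6 down to 0: (0,0) -> (1,1)."""
    _check_nondegenerate(dist)
    points = []
    for c in range(MAX_SCORE + 1, -1, -1):
        tpr = sum(dist.counts_difficult[c:]) / dist.n_difficult
        fpr = sum(dist.counts_easy[c:]) / dist.n_easy
        points.append((fpr, tpr))
    return points


def trapezoid_auc(dist: ScoreDistribution) -> float:
    """Trapezoidal area under the full ordinal empirical ROC."""
    pts = roc_points(dist)
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    return float(np.trapezoid(tpr, fpr))


def concordance_oracle(dist: ScoreDistribution) -> float:
    """AUC by brute-force pair enumeration: P(score_diff > score_easy) + P(tie)/2.

    Independent of the trapezoid path; intended for cross-checking.
    """
    _check_nondegenerate(dist)
    wins = 0.0
    for s_d in range(N_LEVELS):
        nd = dist.counts_difficult[s_d]
        if nd == 0:
            continue
        for s_e in range(N_LEVELS):
            ne = dist.counts_easy[s_e]
            if ne == 0:
                continue
            if s_d > s_e:
                wins += nd * ne
            elif s_d == s_e:
                wins += 0.5 * nd * ne
    return wins / (dist.n_difficult * dist.n_easy)


def binary_auc(table: ContingencyTable2x2) -> float:
    """AUC of the dichotomised classifier: (sensitivity + specificity)/2.

    This is identically the trapezoidal area of the ROC through the single
    operating point (1-specificity, sensitivity).
    """
    m = compute_metrics(table)
    if m.sensitivity is None or m.specificity is None:
        raise ValueError("sensitivity or specificity undefined for this table")
    return (m.sensitivity.value + m.specificity.value) / 2.0


def collapse_to_binary(dist: ScoreDistribution, positivity_threshold: int = 1) -> ScoreDistribution:
    """Collapse the ordinal distribution to scores {0,1} at the positivity cutoff."""
    t = positivity_threshold
    diff = [0] * N_LEVELS
    easy = [0] * N_LEVELS
    diff[0], diff[1] = sum(dist.counts_difficult[:t]), sum(dist.counts_difficult[t:])
    easy[0], easy[1] = sum(dist.counts_easy[:t]), sum(dist.counts_easy[t:])
    return ScoreDistribution(tuple(diff), tuple(easy))


def auc_se(auc: float, n1: int, n2: int) -> float:
    """Hanley-McNeil standard error of an AUC from group sizes n1, n2.

    Uses the exponential approximation Q1 = A/(2-A), Q2 = 2A^2/(1+A).
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must lie in [0,1]")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc) + (n1 - 1) * (q1 - auc * auc) + (n2 - 1) * (q2 - auc * auc)
    ) / (n1 * n2)
    return float(np.sqrt(max(var, 0.0)))


def auc_ci(auc: float, n1: int, n2: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI auc +/- z*se, clipped to [0,1]."""
    se = auc_se(auc, n1, n2)
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


@dataclass(frozen=True)
class ROCResult:
    points: list[tuple[float, float]]
    auc_ordinal: float
    auc_binary: float
    se: float
    ci: tuple[float, float]
    per_cutoff: list[CutoffRow]


def roc_analysis(
    dist: ScoreDistribution, positivity_threshold: int = 1, ci_level: float = 0.95
) -> ROCResult:
    """Full ROC bundle: curve, both AUCs, Hanley-McNeil SE/CI of the binary AUC."""
    rows = cutoff_table(dist)
    binary = trapezoid_auc(collapse_to_binary(dist, positivity_threshold))
    n1, n2 = dist.n_difficult, dist.n_easy
    return ROCResult(
        points=roc_points(dist),
        auc_ordinal=trapezoid_auc(dist),
        auc_binary=binary,
        se=auc_se(binary, n1, n2),
        ci=auc_ci(binary, n1, n2, ci_level),
        per_cutoff=rows,
    )
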