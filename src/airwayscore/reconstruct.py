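"""Deterministic reconstruction of a per-patient cohort from printed margins.

The published report never releases patient-level data, but it fixes, per
reference group, (a) the score histogram — recoverable exactly from the
cumulative sensitivity / 1-specificity percentages — and (b) each
predictor's positive count.  Every reported statistic depends only on
those margins, so any patient-level 0/1 flag matrix with matching row sums
(scores) and column sums (predictor counts) reproduces the entire results
section.  The joint distribution across predictors is under-determined;
the solver returns one canonical exact assignment, seeded for
reproducibility, and reports infeasibility outright rather than a
near-solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .metrics import round_half_up
from .roc import MAX_SCORE, N_LEVELS, ScoreDistribution
from .scoring import (
    PREDICTOR_NAMES,
    PatientAirwayRecord,
    PredictorFlags,
    ScoreThresholds,
    DEFAULT_THRESHOLDS,
)
from . import study


class InfeasibleAssignmentError(ValueError):
    """No 0/1 matrix matches the requested row and column sums."""


def score_counts_from_cumulative(cum_percent: Sequence[float], n: int) -> tuple[int, ...]:
    """Invert cumulative "% with score >= c" (c = 1..5, 1 dp) into per-score counts.

    Each cumulative percentage is converted to a count by half-up rounding
    of p*n/100; counts are then differenced, with score 0 taking the
    remainder.  The inversion self-checks: re-expressing each rounded
    count as a percentage of n at 1 dp must give back the printed value.
    """
    if n <= 0:
        raise ValueError("group size must be positive")
    if len(cum_percent) != MAX_SCORE:
        raise ValueError(f"expected {MAX_SCORE} cumulative percentages (cutoffs 1..{MAX_SCORE})")
    if any(cum_percent[i] < cum_percent[i + 1] for i in range(len(cum_percent) - 1)):
        raise ValueError("cumulative percentages must be non-increasing in the cutoff")
    cum_counts = [int(round_half_up(p * n / 100.0, 0)) for p in cum_percent]
    for p, k in zip(cum_percent, cum_counts):
        back = round_half_up(100.0 * k / n, 1)
        if back != round_half_up(p, 1):
            raise ValueError(
                f"count {k}/{n} re-rounds to {back}%, not the printed {p}% — inversion is ambiguous"
            )
    counts = [n - cum_counts[0]]
    counts += [cum_counts[i] - cum_counts[i + 1] for i in range(MAX_SCORE - 1)]
    counts.append(cum_counts[-1])
    if any(c < 0 for c in counts):
        raise ValueError("cumulative counts are not monotone after rounding")
    return tuple(counts)


def study_score_distribution() -> ScoreDistribution:
    """The study's per-group score histogram, inverted from the cutoff sweep."""
    return ScoreDistribution(
        counts_difficult=score_counts_from_cumulative(
            study.CUMULATIVE_SENSITIVITY_PCT, study.N_DIFFICULT
        ),
        counts_easy=score_counts_from_cumulative(study.CUMULATIVE_FPR_PCT, study.N_EASY),
    )


@dataclass(frozen=True)
class ConsistencyReport:
    """Flag-sum conservation check: histogram-weighted scores vs predictor margins."""

    difficult_from_histogram: int
    difficult_from_marginals: int
    easy_from_histogram: int
    easy_from_marginals: int

    @property
    def passed(self) -> bool:
        return (
            self.difficult_from_histogram == self.difficult_from_marginals
            and self.easy_from_histogram == self.easy_from_marginals
        )


def check_flag_consistency(
    dist: ScoreDistribution,
    difficult_marginals: dict[str, int] | None = None,
    easy_marginals: dict[str, int] | None = None,
) -> ConsistencyReport:
    """Total flags implied by the score histogram must equal the marginal totals."""
    if difficult_marginals is None:
        difficult_marginals = study.DIFFICULT_MARGINALS
    if easy_marginals is None:
        easy_marginals = study.EASY_MARGINALS
    return ConsistencyReport(
        difficult_from_histogram=sum(s * c for s, c in enumerate(dist.counts_difficult)),
        difficult_from_marginals=sum(difficult_marginals.values()),
        easy_from_histogram=sum(s * c for s, c in enumerate(dist.counts_easy)),
        easy_from_marginals=sum(easy_marginals.values()),
    )


def _solve_binary_matrix(row_sums: Sequence[int], col_sums: Sequence[int]) -> np.ndarray:
    """Exact 0/1 matrix with the given row and column sums (Gale-Ryser greedy).

    Rows are satisfied in order of decreasing row sum, each taking the
    columns with the largest remaining demand; for bipartite degree
    sequences this construction succeeds whenever any solution exists.
    """
    n_rows, n_cols = len(row_sums), len(col_sums)
    if any(r < 0 or r > n_cols for r in row_sums):
        raise InfeasibleAssignmentError(f"a row sum is outside 0..{n_cols}")
    if any(c < 0 or c > n_rows for c in col_sums):
        raise InfeasibleAssignmentError(f"a column sum is outside 0..{n_rows}")
    if sum(row_sums) != sum(col_sums):
        raise InfeasibleAssignmentError(
            f"total flags conserved: row sums {sum(row_sums)} != column sums {sum(col_sums)}"
        )
    matrix = np.zeros((n_rows, n_cols), dtype=np.int64)
    remaining = np.asarray(col_sums, dtype=np.int64).copy()
    order = sorted(range(n_rows), key=lambda i: -row_sums[i])
    for i in order:
        r = row_sums[i]
        if r == 0:
            continue
        # columns with largest residual demand; index tie-break for determinism
        cols = sorted(range(n_cols), key=lambda j: (-remaining[j], j))[:r]
        if remaining[cols[-1]] <= 0:
            raise InfeasibleAssignmentError(
                f"cannot place {r} flags for a row: residual column demands {remaining.tolist()}"
            )
        matrix[i, cols] = 1
        remaining[cols] -= 1
    if remaining.any():
        raise InfeasibleAssignmentError(
            f"unmet column demands after assignment: {remaining.tolist()}"
        )
    return matrix


@dataclass(frozen=True)
class FlagAssignment:
    """Per-group patient-level flag vectors, ordered bmi/retrognathia/ulbt/tmd/hmd."""

    difficult: tuple[PredictorFlags, ...]
    easy: tuple[PredictorFlags, ...]

    def score_distribution(self) -> ScoreDistribution:
        diff = [0] * N_LEVELS
        easy = [0] * N_LEVELS
        for f in self.difficult:
            diff[f.total] += 1
        for f in self.easy:
            easy[f.total] += 1
        return ScoreDistribution(tuple(diff), tuple(easy))

    def column_sums(self, group: str) -> dict[str, int]:
        flags = getattr(self, group)
        sums = np.array([f.as_tuple() for f in flags], dtype=np.int64).sum(axis=0) \
            if flags else np.zeros(5, dtype=np.int64)
        return dict(zip(PREDICTOR_NAMES, (int(s) for s in sums)))


def _assign_group(
    counts: Sequence[int], marginals: dict[str, int], rng: np.random.Generator
) -> tuple[PredictorFlags, ...]:
    row_sums = [s for s in range(N_LEVELS) for _ in range(counts[s])]
    col_sums = [marginals[name] for name in PREDICTOR_NAMES]
    matrix = _solve_binary_matrix(row_sums, col_sums)
    # patients with equal scores are exchangeable: the seed permutes them
    # (and therefore which of the feasible row vectors each one carries)
    order = np.arange(len(row_sums))
    for s in range(N_LEVELS):
        idx = [i for i, r in enumerate(row_sums) if r == s]
        order[idx] = rng.permutation(idx)
    return tuple(PredictorFlags(*(int(v) for v in matrix[i])) for i in order)


def assign_flag_vectors(
    dist: ScoreDistribution,
    difficult_marginals: dict[str, int] | None = None,
    easy_marginals: dict[str, int] | None = None,
    seed: int = 0,
) -> FlagAssignment:
    """Patient-level flag matrix matching the score histogram and predictor margins.

    Exact: raises :class:`InfeasibleAssignmentError` (with the violated
    margin) when no assignment exists.  Deterministic given the seed.
    """
    if difficult_marginals is None:
        difficult_marginals = study.DIFFICULT_MARGINALS
    if easy_marginals is None:
        easy_marginals = study.EASY_MARGINALS
    rng = np.random.default_rng(seed)
    return FlagAssignment(
        difficult=_assign_group(dist.counts_difficult, difficult_marginals, rng),
        easy=_assign_group(dist.counts_easy, easy_marginals, rng),
    )


def realize_measurements(
    flags: PredictorFlags,
    difficult: bool,
    rng: np.random.Generator,
    patient_id: str,
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
) -> PatientAirwayRecord:
    """Draw continuous measurements consistent with a flag vector.

    Values are sampled uniformly inside flag-consistent intervals kept
    clear of the cutoffs (then rounded to 2 dp), so re-scoring the record
    recovers the flags exactly.  The MMC sub-class within the difficult
    (3/4) and easy (1/2) pairs is drawn uniformly.
    """
    b = thresholds.bmi_cutoff
    t = thresholds.tmd_cutoff
    h = thresholds.hmd_cutoff
    bmi = rng.uniform(b + 0.5, b + 9.5) if flags.bmi_flag else rng.uniform(19.0, b - 0.5)
    tmd = rng.uniform(t - 2.0, t - 0.1) if flags.tmd_flag else rng.uniform(t + 0.1, t + 2.0)
    hmd = rng.uniform(h - 2.0, h - 0.1) if flags.hmd_flag else rng.uniform(h + 0.1, h + 2.0)
    ulbt = thresholds.ulbt_positive_class if flags.ulbt_flag else int(rng.integers(1, 3))
    mmc = int(rng.integers(3, 5)) if difficult else int(rng.integers(1, 3))
    return PatientAirwayRecord(
        id=patient_id,
        bmi=round(bmi, 2),
        retrognathia=bool(flags.retrognathia_flag),
        ulbt_class=ulbt,
        tmd_cm=round(tmd, 2),
        hmd_cm=round(hmd, 2),
        mmc_class=mmc,
    )


def realize_records(
    assignment: FlagAssignment,
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
    seed: int = 0,
) -> list[PatientAirwayRecord]:
    """Emit a full cohort of raw records whose re-scored flags equal the assignment."""
    rng = np.random.default_rng(seed)
    records = []
    for prefix, flags_list, difficult in (("D", assignment.difficult, True),
                                          ("E", assignment.easy, False)):
        for i, flags in enumerate(flags_list, start=1):
            records.append(
                realize_measurements(flags, difficult, rng, f"{prefix}{i:03d}", thresholds)
            )
    return records


def reconstruct_cohort(
    seed: int = 0, thresholds: ScoreThresholds = DEFAULT_THRESHOLDS
) -> list[PatientAirwayRecord]:
    """End to end: printed margins -> score histogram -> flag matrix -> raw cohort."""
    dist = study_score_distribution()
    report = check_flag_consistency(dist)
    if not report.passed:
        raise InfeasibleAssignmentError(f"margin totals inconsistent: {report}")
    assignment = assign_flag_vectors(dist, seed=seed)
    return realize_records(assignment, thresholds, seed=seed)
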